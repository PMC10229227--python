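"""Gower dissimilarity for binary character matrices with unknown states.

For units i, j let C_ij be the characters scored (known) in both.  Gower's
coefficient for binary presence/absence data reduces to the weighted
mismatch fraction over C_ij:

    D_ij = sum_{c in C_ij} w_c |x_ic - x_jc|  /  sum_{c in C_ij} w_c

Unknown-vs-anything comparisons are dropped from numerator and denominator
(pairwise-complete comparison); the per-character range term is 1 for 0/1
data.  A pair with no comparable characters has no defined distance — by
default that is an error, since ordination downstream needs a complete
matrix, but ``na_policy="allow"`` records it as NaN for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix

__all__ = ["DissimilarityMatrix", "gower", "comparable_counts"]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise Gower distances plus comparable-character counts."""

    unit_ids: list[str]
    values: np.ndarray
    comparable: np.ndarray
    na_policy: str = "error"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.unit_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match unit count")

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def index(self, unit_id: str) -> int:
        return self.unit_ids.index(unit_id)

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy ``pdist`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, unit_ids: list[str]) -> "DissimilarityMatrix":
        idx = [self.index(u) for u in unit_ids]
        return DissimilarityMatrix(
            unit_ids=list(unit_ids),
            values=self.values[np.ix_(idx, idx)].copy(),
            comparable=self.comparable[np.ix_(idx, idx)].copy(),
            na_policy=self.na_policy,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.unit_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        ids = [str(c) for c in df.columns]
        vals = df.to_numpy(dtype=float)
        return cls(unit_ids=ids, values=vals, comparable=np.zeros_like(vals, dtype=int), na_policy="allow")

    @classmethod
    def from_square(cls, unit_ids: list[str], values: np.ndarray) -> "DissimilarityMatrix":
        """Wrap a precomputed square distance matrix (comparability unknown)."""
        values = np.asarray(values, dtype=float)
        counts = np.zeros_like(values, dtype=int)
        return cls(unit_ids=list(unit_ids), values=values, comparable=counts, na_policy="allow")


def comparable_counts(matrix: CharacterMatrix) -> np.ndarray:
    """Number of characters scored (known) in both units, per unit pair.

    The diagonal holds each unit's own count of known states.
    """
    known = (~np.isnan(matrix.states)).astype(float)
    return (known @ known.T).astype(int)


def gower(matrix: CharacterMatrix, na_policy: str = "error") -> DissimilarityMatrix:
    """Compute the pairwise Gower dissimilarity matrix.

    Parameters
    ----------
    matrix : CharacterMatrix
        At least two units; states in {0, 1, unknown}.
    na_policy : {"error", "allow"}
        What to do when a pair shares no comparable characters.

    Returns
    -------
    DissimilarityMatrix
        Distances in [0, 1]; ``comparable`` carries |C_ij|.
    """
    if na_policy not in ("error", "allow"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    if matrix.n_units < 2:
        raise ValueError("Gower requires at least 2 units")

    X = matrix.states
    w = matrix.weights
    known = ~np.isnan(X)
    K = known.astype(float)
    P = np.where(known, X, 0.0)          # presence indicator, unknowns zeroed
    A = np.where(known, 1.0 - X, 0.0)    # absence indicator

    Kw = K * w
    Pw = P * w
    # weighted mismatches: present-in-i & absent-in-j plus the converse
    mism = Pw @ A.T + (A * w) @ P.T
    denom = Kw @ K.T
    counts = (K @ K.T).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, mism / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against fp noise

    if na_policy == "error":
        bad = np.argwhere(np.isnan(D))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"units {matrix.units[i].unit_id!r} and {matrix.units[j].unit_id!r} share no "
                "comparable characters; recode (coding style 2) or use na_policy='allow'"
            )
    return DissimilarityMatrix(
        unit_ids=matrix.unit_ids, values=D, comparable=counts, na_policy=na_policy
    )
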