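"""Ordination of dissimilarity matrices: non-metric MDS and PCoA.

NMDS searches for a k-dimensional configuration whose inter-point distances
are monotonically related to the observed dissimilarities, minimizing
Kruskal's stress-1

    stress = sqrt( sum_{i<j} (dist_ij - dhat_ij)^2 / sum_{i<j} dist_ij^2 )

where the disparities dhat are the weighted least-squares monotone
(isotonic) regression of configuration distances on observed
dissimilarities.  The engine is SMACOF-style majorization: each iteration
refits the disparities by pool-adjacent-violators and moves the
configuration by a Guttman transform.  Ties in the observed dissimilarities
are handled by Kruskal's primary approach (tied observations may receive
different fitted values; within a tie block the pairs are ordered by
current configuration distance).

PCoA (classical metric scaling) eigendecomposes the double-centered squared
dissimilarity matrix; the Cailliez correction adds the smallest constant to
all off-diagonal dissimilarities that makes them Euclidean-embeddable,
removing negative eigenvalues caused by missing data or non-Euclidean
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "ShepardData",
    "NMDSResult",
    "PCoAResult",
    "pava",
    "kruskal_stress",
    "nmds",
    "cailliez_constant",
    "pcoa",
    "normalize_coordinates",
]


# ---------------------------------------------------------------------------
# Monotone regression
# ---------------------------------------------------------------------------


def pava(y, weights=None) -> np.ndarray:
    """Weighted least-squares non-decreasing fit by pool-adjacent-violators.

    Returns the non-decreasing sequence minimizing sum w_i (y_i - f_i)^2.
    The fit preserves the weighted mean of ``y``.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("pava requires a non-empty sequence")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match y in length")

    # blocks as (mean, weight, count), merged while out of order
    means = []
    wts = []
    counts = []
    for yi, wi in zip(y, w):
        means.append(yi)
        wts.append(wi)
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), counts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), counts.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wts.append(wt)
            counts.append(c1 + c2)
    out = np.empty_like(y)
    pos = 0
    for m, c in zip(means, counts):
        out[pos : pos + c] = m
        pos += c
    return out


# ---------------------------------------------------------------------------
# Stress and Shepard diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ShepardData:
    """Per unit pair: observed dissimilarity, configuration distance, and the
    monotone-fitted distance.  Rows are sorted by observed dissimilarity
    (ties by configuration distance), so ``fitted`` is non-decreasing."""

    pair_indices: np.ndarray  # (n_pairs, 2) unit indices i < j
    observed: np.ndarray
    distances: np.ndarray
    fitted: np.ndarray


def _as_condensed(D: DissimilarityMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(D, DissimilarityMatrix):
        vals = D.values
    else:
        vals = np.asarray(D, dtype=float)
    n = vals.shape[0]
    iu = np.triu_indices(n, k=1)
    d = vals[iu]
    if np.isnan(d).any():
        raise ValueError(
            "dissimilarity matrix contains NA entries; recode with coding style 2 "
            "or recompute with na_policy='error' satisfied"
        )
    return d, n


def kruskal_stress(D: DissimilarityMatrix | np.ndarray, coordinates) -> tuple[float, ShepardData]:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Disparities come from the monotone regression of configuration distances
    on observed dissimilarities (primary tie handling).
    """
    d_obs, n = _as_condensed(D)
    X = np.asarray(coordinates, dtype=float)
    if X.shape[0] != n:
        raise ValueError("coordinate rows must match dissimilarity matrix size")
    dist = pdist(X)
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu)

    order = np.lexsort((dist, d_obs))
    fitted_sorted = pava(dist[order])
    denom = float(np.sum(dist**2))
    if denom == 0.0:
        stress = 0.0 if np.allclose(d_obs, 0) else float("inf")
    else:
        stress = float(np.sqrt(np.sum((dist[order] - fitted_sorted) ** 2) / denom))
    shepard = ShepardData(
        pair_indices=pairs[order],
        observed=d_obs[order],
        distances=dist[order],
        fitted=fitted_sorted,
    )
    return stress, shepard


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float
    k: int
    n_starts: int
    seed: Optional[int]
    best_start_index: int
    iterations_used: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    all_stresses: list[float] = field(default_factory=list)
    shepard: Optional[ShepardData] = None
    unit_ids: Optional[list[str]] = None


def normalize_coordinates(X: np.ndarray) -> np.ndarray:
    """Pin the ordination gauge: center, rotate to principal axes, fix signs.

    Reflection and rotation are gauge freedoms of (N)MDS — two runs can
    legitimately return axis-inverted configurations.  Centering columns,
    rotating onto the principal axes of the configuration, and making the
    entry of largest magnitude on each axis positive yields a canonical
    representative, so equal-stress solutions compare equal in tests.
    """
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    # principal-axis rotation via SVD of the centered configuration
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for j in range(X.shape[1]):
        col = X[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            X[:, j] = -col
    return X


def _disparities(d_obs: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Monotone-fitted disparities in original pair order (primary ties).

    Disparities are rescaled to a fixed sum of squares: raw stress scales
    quadratically under uniform shrinkage of the configuration, so without
    this normalization the majorization drifts toward total collapse.
    """
    order = np.lexsort((dist, d_obs))
    fitted = pava(dist[order])
    out = np.empty_like(fitted)
    out[order] = fitted
    scaled = out.copy()
    ss = float(np.sum(scaled**2))
    if ss > 0:
        scaled *= np.sqrt(scaled.size / ss)
    return out, scaled


def _guttman_transform(X: np.ndarray, dhat: np.ndarray, dist: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    ratio = np.zeros_like(dist)
    nz = dist > 1e-12
    ratio[nz] = dhat[nz] / dist[nz]
    B = -squareform(ratio)
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def nmds(
    D: DissimilarityMatrix | np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: Optional[int] = None,
    unit_ids: Optional[list[str]] = None,
) -> NMDSResult:
    """Non-metric multidimensional scaling by majorization.

    The first start is initialized from the PCoA configuration (a standard
    convention); the remaining ``n_starts - 1`` starts draw uniform(-1, 1)
    coordinates from a seeded generator.  The lowest-stress solution is
    returned, with coordinates normalized by :func:`normalize_coordinates`.

    Parameters
    ----------
    D : DissimilarityMatrix or square array
        Complete symmetric dissimilarities.
    k : int
        Target dimensionality, 1 <= k < number of units.
    tol : float
        Convergence threshold on the relative stress decrease per iteration.
    """
    d_obs, n = _as_condensed(D)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of units ({n})")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if unit_ids is None and isinstance(D, DissimilarityMatrix):
        unit_ids = list(D.unit_ids)

    rng = np.random.default_rng(seed)
    sqD = squareform(d_obs)

    inits: list[np.ndarray] = []
    pcoa_res = pcoa(sqD, correction="none", unit_ids=unit_ids)
    Xp = pcoa_res.coordinates
    if Xp.shape[1] >= k:
        inits.append(Xp[:, :k].copy())
    else:  # degenerate D with fewer positive axes than k: pad with noise
        pad = rng.uniform(-1e-3, 1e-3, size=(n, k - Xp.shape[1]))
        inits.append(np.hstack([Xp, pad]))
    for _ in range(n_starts - 1):
        inits.append(rng.uniform(-1.0, 1.0, size=(n, k)))

    best = None
    stresses: list[float] = []
    iters: list[int] = []
    convs: list[bool] = []
    for X0 in inits:
        X = X0 - X0.mean(axis=0, keepdims=True)
        dist = pdist(X)
        fit, dhat = _disparities(d_obs, dist)
        denom = float(np.sum(dist**2))
        stress = np.sqrt(np.sum((dist - fit) ** 2) / denom) if denom > 0 else np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            X_new = _guttman_transform(X, dhat, dist)
            dist_new = pdist(X_new)
            fit_new, dhat_new = _disparities(d_obs, dist_new)
            denom = float(np.sum(dist_new**2))
            stress_new = (
                np.sqrt(np.sum((dist_new - fit_new) ** 2) / denom) if denom > 0 else np.inf
            )
            if stress_new > stress:  # majorization overshoot at numerical floor
                converged = True
                break
            X, dist, dhat = X_new, dist_new, dhat_new
            if stress - stress_new < tol * max(stress, 1e-30):
                stress = stress_new
                converged = True
                break
            stress = stress_new
        stresses.append(float(stress))
        iters.append(it)
        convs.append(converged)
        if best is None or stress < best[0]:
            best = (float(stress), X)

    best_idx = int(np.argmin(stresses))
    X_best = normalize_coordinates(best[1])
    # pin the scale gauge too: configuration distances live on the scale of
    # the observed dissimilarities (exact in the Euclidean limit)
    ss_dist = float(np.sum(pdist(X_best) ** 2))
    if ss_dist > 0:
        X_best *= np.sqrt(float(np.sum(d_obs**2)) / ss_dist)
    stress_final, shepard = kruskal_stress(sqD, X_best)
    return NMDSResult(
        coordinates=X_best,
        stress=stress_final,
        k=k,
        n_starts=n_starts,
        seed=seed,
        best_start_index=best_idx,
        iterations_used=iters,
        converged=convs,
        all_stresses=stresses,
        shepard=shepard,
        unit_ids=unit_ids,
    )


# ---------------------------------------------------------------------------
# PCoA with Cailliez correction
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    cailliez_constant: float
    proportion_explained: np.ndarray
    unit_ids: Optional[list[str]] = None


def _center(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ M @ J


def cailliez_constant(D: DissimilarityMatrix | np.ndarray) -> float:
    """Smallest c >= 0 such that d_ij + c (i != j) is Euclidean-embeddable.

    Computed as the largest real eigenvalue of the standard 2n x 2n
    companion matrix built from the double-centered -D^2/2 and -D/2 blocks;
    zero when the input is already Euclidean.
    """
    d, n = _as_condensed(D)
    vals = squareform(d)
    if n <= 2:
        return 0.0
    delta1 = _center(-0.5 * vals**2)
    delta2 = _center(-0.5 * vals)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    companion = np.vstack([upper, lower])
    eigs = scipy.linalg.eigvals(companion)
    real = eigs.real[np.abs(eigs.imag) < 1e-8 * max(1.0, np.abs(eigs).max())]
    c = float(real.max()) if real.size else 0.0
    return max(c, 0.0)


def pcoa(
    D: DissimilarityMatrix | np.ndarray,
    correction: str = "none",
    unit_ids: Optional[list[str]] = None,
) -> PCoAResult:
    """Principal coordinates analysis (classical metric MDS).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the non-negative eigenvalues.  With
    ``correction="cailliez"`` the constant is added to off-diagonal
    dissimilarities first, which guarantees no eigenvalue below numerical
    tolerance.  ``proportion_explained`` is taken over positive eigenvalues.
    """
    d, n = _as_condensed(D)
    if unit_ids is None and isinstance(D, DissimilarityMatrix):
        unit_ids = list(D.unit_ids)
    vals = squareform(d)

    if correction == "cailliez":
        c = cailliez_constant(vals)
        if c > 0:
            vals = squareform(squareform(vals) + c)
    elif correction == "none":
        c = 0.0
    else:
        raise ValueError(f"unknown correction {correction!r}; expected 'none' or 'cailliez'")

    B = _center(-0.5 * vals**2)
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = 1e-10 * max(1.0, np.abs(eigvals).max())
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    # deterministic sign: largest-magnitude loading positive on each axis
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col

    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigvals,
        cailliez_constant=c,
        proportion_explained=prop,
        unit_ids=unit_ids,
    )
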