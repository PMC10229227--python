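"""Core domain types for binary morphological character matrices.

The analytical unit here is not a species but a *snapshot* of an organism:
a semaphoront (an individual at one ontogenetic stage, after Hennig) or a
semataphont (an individual after a given amount of post-mortem decay).
Fossil specimens, and alternative anatomical interpretations of the same
fossil ("versions"), are further unit classes.  Every unit carries a row of
binary character states — present (1), absent (0) or unknown (?) — plus the
stage metadata needed to order it along the ontogenetic or taphonomic axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "UNIT_CLASSES",
    "STATE_SYMBOLS",
    "UnitRecord",
    "CharacterMatrix",
    "ValidationReport",
    "validate",
    "apply_coding_style",
    "states_from_symbols",
    "symbols_from_states",
]

#: Admissible unit classes.  ``fossil_version`` marks alternative anatomical
#: interpretations of the same fossil under different homology models.
UNIT_CLASSES = ("semaphoront", "semataphont", "fossil_specimen", "fossil_version")

EXTANT_CLASSES = ("semaphoront", "semataphont")
FOSSIL_CLASSES = ("fossil_specimen", "fossil_version")

#: Serialization symbols for the three admissible character states.
STATE_SYMBOLS = ("0", "1", "?")

_SYMBOL_TO_STATE = {"0": 0.0, "1": 1.0, "?": math.nan}


def states_from_symbols(symbols: Iterable[str]) -> np.ndarray:
    """Map state symbols '0'/'1'/'?' to a float vector (unknown -> NaN)."""
    out = []
    for s in symbols:
        s = str(s).strip()
        if s not in _SYMBOL_TO_STATE:
            raise ValueError(f"invalid character state symbol {s!r}; expected one of 0, 1, ?")
        out.append(_SYMBOL_TO_STATE[s])
    return np.asarray(out, dtype=float)


def symbols_from_states(states: np.ndarray) -> list[str]:
    """Inverse of :func:`states_from_symbols` for a 1-D state vector."""
    out = []
    for v in np.asarray(states, dtype=float).ravel():
        if math.isnan(v):
            out.append("?")
        elif v == 0.0:
            out.append("0")
        elif v == 1.0:
            out.append("1")
        else:
            raise ValueError(f"invalid internal state value {v!r}")
    return out


@dataclass
class UnitRecord:
    """Metadata for one taxonomic unit (one row of the matrix).

    Parameters
    ----------
    unit_id : str
        Unique identifier within a matrix.
    taxon : str
        The organism the unit was derived from.
    unit_class : str
        One of :data:`UNIT_CLASSES`.
    ontogenetic_rank : int or None
        Ordinal position in the taxon's developmental series (0-based).
        Required for semaphoronts.
    decay_stage : int or None
        Decay stage, 0 = undecayed.  Semataphonts have stage >= 1; a
        semaphoront may carry 0 or None.
    label : str
        Free-text display label.
    """

    unit_id: str
    taxon: str = ""
    unit_class: str = "fossil_specimen"
    ontogenetic_rank: Optional[int] = None
    decay_stage: Optional[int] = None
    label: str = ""

    def copy(self) -> "UnitRecord":
        return replace(self)


@dataclass
class CharacterMatrix:
    """Units x binary characters with {0, 1, ?} states and stage metadata.

    States are stored as a float array with NaN encoding the unknown state;
    this makes pairwise-complete comparisons (Gower) a masked-array exercise
    rather than a triple-valued logic one.
    """

    characters: list[str]
    units: list[UnitRecord]
    states: np.ndarray
    character_labels: Optional[list[str]] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape != (len(self.units), len(self.characters)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.units)} units x {len(self.characters)} characters"
            )
        if self.weights is None:
            self.weights = np.ones(len(self.characters))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.characters),):
                raise ValueError("one weight per character required")
        if self.character_labels is None:
            self.character_labels = list(self.characters)

    # -- basic access -----------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit_index(self, unit_id: str) -> int:
        for i, u in enumerate(self.units):
            if u.unit_id == unit_id:
                return i
        raise KeyError(f"unknown unit_id {unit_id!r}")

    def unit(self, unit_id: str) -> UnitRecord:
        return self.units[self.unit_index(unit_id)]

    def row(self, unit_id: str) -> np.ndarray:
        return self.states[self.unit_index(unit_id)]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            characters=list(self.characters),
            units=[u.copy() for u in self.units],
            states=self.states.copy(),
            character_labels=list(self.character_labels),
            weights=self.weights.copy(),
        )

    def subset_units(self, unit_ids: Sequence[str]) -> "CharacterMatrix":
        idx = [self.unit_index(u) for u in unit_ids]
        return CharacterMatrix(
            characters=list(self.characters),
            units=[self.units[i].copy() for i in idx],
            states=self.states[idx].copy(),
            character_labels=list(self.character_labels),
            weights=self.weights.copy(),
        )

    def extant_unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units if u.unit_class in EXTANT_CLASSES]

    def fossil_unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units if u.unit_class in FOSSIL_CLASSES]

    def append_unit(self, record: UnitRecord, states: np.ndarray) -> None:
        states = np.asarray(states, dtype=float).reshape(-1)
        if states.shape != (self.n_characters,):
            raise ValueError("state vector length does not match character count")
        self.units.append(record)
        self.states = np.vstack([self.states, states[None, :]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.characters == other.characters
            and self.units == other.units
            and np.array_equal(self.states, other.states, equal_nan=True)
            and np.allclose(self.weights, other.weights)
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: errors, warnings and a unit census."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def error_codes(self) -> list[str]:
        return [code for code, _, _ in self.errors]


def validate(matrix: CharacterMatrix) -> ValidationReport:
    """Check every structural invariant of a character matrix.

    Violations are report content, not exceptions: a matrix is *valid* iff
    the report's error list is empty.  The counts section (units per class,
    fraction of unknown states) is always populated.
    """
    report = ValidationReport()
    err = report.errors.append

    seen: set[str] = set()
    for u in matrix.units:
        locus = f"unit {u.unit_id!r}"
        if u.unit_id in seen:
            err(("DUPLICATE_UNIT", f"duplicate unit_id {u.unit_id!r}", locus))
        seen.add(u.unit_id)
        if u.unit_class not in UNIT_CLASSES:
            err(("BAD_UNIT_CLASS", f"unknown unit_class {u.unit_class!r}", locus))
            continue
        if u.unit_class == "semaphoront":
            if u.ontogenetic_rank is None:
                err(("MISSING_ONTOGENETIC_RANK", "semaphoront lacks ontogenetic_rank", locus))
            elif u.ontogenetic_rank < 0:
                err(("BAD_ONTOGENETIC_RANK", "ontogenetic_rank must be >= 0", locus))
            if u.decay_stage not in (None, 0):
                err(
                    (
                        "SEMAPHORONT_DECAYED",
                        f"semaphoront has decay_stage={u.decay_stage}; must be unset or 0",
                        locus,
                    )
                )
        elif u.unit_class == "semataphont":
            if u.decay_stage is None or u.decay_stage < 1:
                err(("BAD_DECAY_STAGE", "semataphont requires decay_stage >= 1", locus))

    seen_chars: set[str] = set()
    for c in matrix.characters:
        if c in seen_chars:
            err(("DUPLICATE_CHARACTER", f"duplicate character id {c!r}", f"character {c!r}"))
        seen_chars.add(c)

    if np.any(matrix.weights <= 0):
        bad = [matrix.characters[i] for i in np.flatnonzero(matrix.weights <= 0)]
        err(("BAD_WEIGHT", f"non-positive weight for characters {bad}", "weights"))

    finite = matrix.states[~np.isnan(matrix.states)]
    if finite.size and not np.all(np.isin(finite, (0.0, 1.0))):
        err(("BAD_STATE", "states must be 0, 1 or unknown", "states"))

    counts = {cls: 0 for cls in UNIT_CLASSES}
    for u in matrix.units:
        if u.unit_class in counts:
            counts[u.unit_class] += 1
    report.counts = {
        "n_units": matrix.n_units,
        "n_characters": matrix.n_characters,
        "units_per_class": counts,
        "fraction_unknown": float(np.isnan(matrix.states).mean()) if matrix.states.size else 0.0,
    }
    return report


def apply_coding_style(matrix: CharacterMatrix, style: int | str) -> CharacterMatrix:
    """Apply one of the two fossil coding styles.

    Style 1 tolerates unknown states (0/1/?) and returns the matrix as-is.
    Style 2 is the strict presence/absence approach: every unknown state is
    mechanically recoded as absent (0), so its output contains no '?'.  The
    recoding is idempotent.
    """
    style = str(style).lstrip("style")
    if style == "1":
        return matrix.copy()
    if style == "2":
        out = matrix.copy()
        out.states = np.where(np.isnan(out.states), 0.0, out.states)
        return out
    raise ValueError(f"unknown coding style {style!r}; expected 1 or 2")
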