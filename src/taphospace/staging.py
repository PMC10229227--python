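"""Deriving ontogenetic and taphonomic unit series, and simulating them.

A semaphoront series is generated by an :class:`OntogenySchedule`: each
character is present during a half-open interval of developmental ranks
(traits accumulate through development; larval traits can be lost at
metamorphosis).  A semataphont series is generated by a
:class:`DecaySchedule`: each character is lost at a fixed decay stage (or
never), so the present-character sets are nested and shrink monotonically —
the "linear loss" decay paradigm.  Decay-resistant traits shared across
taxa are lost last (or never), which is what drives decayed units from
different taxa to converge in morphospace (stem-ward slippage).  The
``labile_last`` retention rule inverts the loss order to emulate
preservational regimes where decay-prone tissue is preferentially
preserved.

:func:`simulate_framework` assembles a full comparative framework — taxa x
ontogenetic stages x decay stages plus synthetic fossil specimens — from a
:class:`FrameworkConfig`; all randomness flows from one seed, split per
taxon and per character block so adding a taxon does not perturb the draws
of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .matrix import CharacterMatrix, UnitRecord

__all__ = [
    "NEVER",
    "DecaySchedule",
    "OntogenySchedule",
    "LossRule",
    "TaxonConfig",
    "FossilGroupConfig",
    "FrameworkConfig",
    "derive_semataphonts",
    "derive_semaphoronts",
    "simulate_framework",
    "make_synthetic_fossil",
    "load_framework_config",
    "table1_config",
]

#: Sentinel loss stage for characters retained through the final decay stage.
NEVER = None


@dataclass
class DecaySchedule:
    """Per-character decay loss ranks for one taxon.

    ``loss_stage[c]`` is the stage (1..max_stage) at which character ``c``
    is lost, or ``None`` (NEVER) for decay-resistant characters retained
    through the terminal stage.  Loss is nested and monotone: lost at stage
    k means absent at every stage >= k.
    """

    taxon: str
    max_stage: int
    loss_stage: list[Optional[int]]

    def __post_init__(self) -> None:
        if self.max_stage < 1:
            raise ValueError("max_stage must be >= 1")
        for s in self.loss_stage:
            if s is not None and not (1 <= s <= self.max_stage):
                raise ValueError(f"loss stage {s} outside 1..{self.max_stage}")


@dataclass
class OntogenySchedule:
    """Per-character presence intervals over developmental ranks 0..R-1.

    Character ``c`` is present at rank r iff acquire[c] <= r < lose[c];
    ``lose = R + 1`` means never lost during life.
    """

    taxon: str
    n_stages: int
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        for a, b in self.intervals:
            if not (0 <= a < b <= self.n_stages + 1):
                raise ValueError(f"interval [{a},{b}) violates 0 <= a < b <= R+1")


@dataclass
class LossRule:
    """How decay-lost characters are scored.

    ``score_absent`` (extant semataphonts: the experimental observer sees a
    real absence) or ``score_unknown`` (fossil-style ambiguity, coded '?').
    """

    lost_state_policy: str = "score_absent"

    def __post_init__(self) -> None:
        if self.lost_state_policy not in ("score_absent", "score_unknown"):
            raise ValueError(f"unknown lost_state_policy {self.lost_state_policy!r}")

    @property
    def lost_value(self) -> float:
        return 0.0 if self.lost_state_policy == "score_absent" else math.nan


def derive_semataphonts(
    adult_states: np.ndarray, schedule: DecaySchedule, rule: LossRule = LossRule()
) -> list[tuple[int, np.ndarray]]:
    """Divide one unit into its decay-stage series.

    Returns ``[(stage, states), ...]`` for stages 1..max_stage; at stage k
    every character with loss_stage <= k is set per the loss rule, all
    other states are copied.
    """
    adult_states = np.asarray(adult_states, dtype=float)
    if adult_states.shape != (len(schedule.loss_stage),):
        raise ValueError(
            f"state vector length {adult_states.shape} does not match schedule "
            f"({len(schedule.loss_stage)} characters)"
        )
    out = []
    for k in range(1, schedule.max_stage + 1):
        v = adult_states.copy()
        for c, s in enumerate(schedule.loss_stage):
            if s is not None and s <= k:
                v[c] = rule.lost_value
        out.append((k, v))
    return out


def derive_semaphoronts(schedule: OntogenySchedule) -> list[tuple[int, np.ndarray]]:
    """Expand an ontogeny schedule into its semaphoront series.

    Returns ``[(rank, states), ...]`` for ranks 0..R-1 with presence per
    the interval rule.
    """
    out = []
    for r in range(schedule.n_stages):
        v = np.array([1.0 if a <= r < b else 0.0 for a, b in schedule.intervals])
        out.append((r, v))
    return out


# ---------------------------------------------------------------------------
# Framework simulation
# ---------------------------------------------------------------------------


@dataclass
class TaxonConfig:
    """One extant taxon: its developmental series and which of its
    ontogenetic stages are subjected to the decay series."""

    name: str
    n_onto_stages: int = 1
    decayed_stages: Optional[list[int]] = None  # default: adult (last rank) only

    def resolved_decayed(self) -> list[int]:
        if self.decayed_stages is None:
            return [self.n_onto_stages - 1]
        return list(self.decayed_stages)


@dataclass
class FossilGroupConfig:
    """A group of synthetic fossil specimens derived from the extant
    framework by decay plus random obscuring of remaining characters."""

    name: str
    count: int = 1
    source_taxon: Optional[str] = None  # default: cycle through taxa
    decay_stage: Optional[int] = None  # default: random stage per specimen
    obscure_fraction: float = 0.3
    unit_class: str = "fossil_specimen"


@dataclass
class FrameworkConfig:
    """Generative settings for a synthetic comparative framework.

    ``fraction_shared_resistant`` of the characters are present in every
    taxon and survive decay longest; ``fraction_apomorphic`` are private to
    a single taxon and are lost early (under the default ``resistant_last``
    rule) — the combination that produces stem-ward slippage.  The
    remaining characters get random taxon occupancy, random ontogeny and
    intermediate decay resistance.
    """

    n_taxa: int = 4
    n_chars: int = 71
    n_onto_stages: int | Sequence[int] = 3
    n_decay_stages: int = 6
    fraction_shared_resistant: float = 0.3
    fraction_apomorphic: float = 0.3
    retention_rule: str = "resistant_last"
    seed: int = 0
    taxa: Optional[list[TaxonConfig]] = None
    fossils: list[FossilGroupConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_chars < 1 or self.n_decay_stages < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.fraction_shared_resistant <= 1 and 0 <= self.fraction_apomorphic <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_shared_resistant + self.fraction_apomorphic > 1:
            raise ValueError("fraction_shared_resistant + fraction_apomorphic must be <= 1")
        if self.retention_rule not in ("resistant_last", "labile_last"):
            raise ValueError(f"unknown retention_rule {self.retention_rule!r}")

    def resolved_taxa(self) -> list[TaxonConfig]:
        if self.taxa is not None:
            return self.taxa
        if isinstance(self.n_onto_stages, int):
            stages = [self.n_onto_stages] * self.n_taxa
        else:
            stages = list(self.n_onto_stages)
            if len(stages) != self.n_taxa:
                raise ValueError("n_onto_stages sequence length must equal n_taxa")
        return [TaxonConfig(name=f"taxon{i + 1}", n_onto_stages=stages[i]) for i in range(self.n_taxa)]


@dataclass
class SimulatedFramework:
    """A simulated matrix together with the schedules that generated it."""

    matrix: CharacterMatrix
    decay_schedules: dict[str, DecaySchedule]
    ontogeny_schedules: dict[str, OntogenySchedule]
    shared_resistant: list[str]
    apomorphic: dict[str, list[str]]
    config: FrameworkConfig


def _char_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0]))


def _taxon_rng(seed: int, taxon_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1 + taxon_index]))


def _assign_loss_stages(
    resistance: np.ndarray, never_mask: np.ndarray, S: int, rule: str
) -> list[Optional[int]]:
    """Map character resistance scores to loss stages 1..S (or NEVER).

    Under ``resistant_last`` the most labile characters go first and the
    ``never_mask`` characters are never lost; ``labile_last`` inverts the
    ordering, so the formerly most-resistant characters are lost first and
    an equally-sized block of the most labile ones is retained.
    """
    n = resistance.size
    loss: list[Optional[int]] = [None] * n
    if rule == "resistant_last":
        mortal = np.flatnonzero(~never_mask)
        order = mortal[np.argsort(resistance[mortal], kind="stable")]
    else:
        n_keep = int(never_mask.sum())
        order_all = np.argsort(-resistance, kind="stable")
        keep = set(order_all[n - n_keep :].tolist()) if n_keep else set()
        order = np.array([i for i in order_all if i not in keep], dtype=int)
        for i in keep:
            loss[i] = None
    if order.size:
        bins = np.array_split(order, S)
        for k, idx in enumerate(bins, start=1):
            for i in idx:
                loss[i] = k
    return loss


def simulate_framework(config: FrameworkConfig) -> SimulatedFramework:
    """Simulate a complete semaphoront + semataphont + fossil framework.

    Deterministic under ``config.seed``.  Emits, per taxon, one semaphoront
    per ontogenetic rank and, for each designated decayed rank, semataphonts
    for decay stages 1..S (decay-lost characters scored absent, as for
    experimentally observed extant decay).  Fossil groups are then derived
    from the extant units with decay losses and obscured characters scored
    unknown.
    """
    taxa = config.resolved_taxa()
    n_chars = config.n_chars
    S = config.n_decay_stages
    characters = [f"c{i + 1}" for i in range(n_chars)]

    crng = _char_rng(config.seed)
    n_shared = int(round(config.fraction_shared_resistant * n_chars))
    n_apo = int(round(config.fraction_apomorphic * n_chars))
    perm = crng.permutation(n_chars)
    shared_idx = np.sort(perm[:n_shared])
    apo_idx = np.sort(perm[n_shared : n_shared + n_apo])
    shared_mask = np.zeros(n_chars, dtype=bool)
    shared_mask[shared_idx] = True

    # decay resistance is a property of the trait, common across taxa, so a
    # character present in two taxa decays at the same stage in both
    resistance = crng.uniform(0.0, 1.0, size=n_chars)
    resistance[shared_idx] += 2.0  # shared characters are the decay-resistant tier
    resistance[apo_idx] -= 2.0  # apomorphies are the most labile tier
    loss = _assign_loss_stages(resistance, shared_mask, S, config.retention_rule)

    # apomorphy ownership round-robins over taxa
    apo_owner = {int(c): i % len(taxa) for i, c in enumerate(apo_idx)}
    apomorphic: dict[str, list[str]] = {t.name: [] for t in taxa}
    for c, owner in apo_owner.items():
        apomorphic[taxa[owner].name].append(characters[c])

    matrix = CharacterMatrix(
        characters=characters,
        units=[],
        states=np.empty((0, n_chars)),
    )
    decay_schedules: dict[str, DecaySchedule] = {}
    onto_schedules: dict[str, OntogenySchedule] = {}

    for ti, taxon in enumerate(taxa):
        trng = _taxon_rng(config.seed, ti)
        R = taxon.n_onto_stages
        intervals: list[tuple[int, int]] = []
        for c in range(n_chars):
            if shared_mask[c]:
                intervals.append((0, R + 1))  # framework backbone: always on
            elif c in apo_owner:
                if apo_owner[c] == ti:
                    intervals.append((0, R + 1))
                else:
                    intervals.append((R, R + 1))  # empty at every rank 0..R-1
            else:
                if trng.random() < 0.6:  # taxon possesses this background character
                    acquire = int(trng.integers(0, R)) if R > 1 and trng.random() < 0.5 else 0
                    if acquire + 1 < R and trng.random() < 0.15:  # larval trait lost in life
                        lose = int(trng.integers(acquire + 1, R))
                    else:
                        lose = R + 1
                    intervals.append((acquire, lose))
                else:
                    intervals.append((R, R + 1))
        # (R, R+1) encodes "never present at ranks 0..R-1"
        sched_o = OntogenySchedule(taxon=taxon.name, n_stages=R, intervals=intervals)
        sched_d = DecaySchedule(taxon=taxon.name, max_stage=S, loss_stage=list(loss))
        onto_schedules[taxon.name] = sched_o
        decay_schedules[taxon.name] = sched_d

        stages = derive_semaphoronts(sched_o)
        for r, v in stages:
            matrix.append_unit(
                UnitRecord(
                    unit_id=f"{taxon.name}_onto{r}",
                    taxon=taxon.name,
                    unit_class="semaphoront",
                    ontogenetic_rank=r,
                    decay_stage=0,
                    label=f"{taxon.name} ontogenetic stage {r}",
                ),
                v,
            )
        for r in taxon.resolved_decayed():
            if not (0 <= r < R):
                raise ValueError(f"decayed stage {r} outside ontogenetic ranks of {taxon.name}")
            base = stages[r][1]
            for k, v in derive_semataphonts(base, sched_d, LossRule("score_absent")):
                matrix.append_unit(
                    UnitRecord(
                        unit_id=f"{taxon.name}_onto{r}_decay{k}",
                        taxon=taxon.name,
                        unit_class="semataphont",
                        ontogenetic_rank=r,
                        decay_stage=k,
                        label=f"{taxon.name} stage-{r} semaphoront, decay stage {k}",
                    ),
                    v,
                )

    framework = SimulatedFramework(
        matrix=matrix,
        decay_schedules=decay_schedules,
        ontogeny_schedules=onto_schedules,
        shared_resistant=[characters[int(c)] for c in shared_idx],
        apomorphic=apomorphic,
        config=config,
    )

    for gi, group in enumerate(config.fossils):
        grng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000 + gi]))
        for j in range(group.count):
            taxon = group.source_taxon or taxa[(gi + j) % len(taxa)].name
            stage = group.decay_stage or int(grng.integers(1, S + 1))
            rec, states = make_synthetic_fossil(
                matrix,
                taxon=taxon,
                decay_stage=stage,
                obscure_fraction=group.obscure_fraction,
                seed=int(grng.integers(0, 2**31 - 1)),
            )
            rec.unit_id = f"{group.name}_{j + 1}" if group.count > 1 else group.name
            rec.unit_class = group.unit_class
            rec.label = f"synthetic fossil ({group.name}) from {taxon} decay stage {stage}"
            matrix.append_unit(rec, states)

    return framework


def make_synthetic_fossil(
    matrix: CharacterMatrix,
    taxon: str,
    decay_stage: int,
    obscure_fraction: float = 0.0,
    seed: int = 0,
    ontogenetic_rank: Optional[int] = None,
) -> tuple[UnitRecord, np.ndarray]:
    """Turn a semataphont into a synthetic fossil specimen.

    Copies the chosen semataphont; characters lost to decay (absent in the
    semataphont, present in its undecayed source semaphoront) become
    unknown, as does a random ``obscure_fraction`` of the remaining known
    characters.  The returned record has unit_class ``fossil_specimen``
    with both stage fields unset.
    """
    cands = [
        u
        for u in matrix.units
        if u.unit_class == "semataphont"
        and u.taxon == taxon
        and u.decay_stage == decay_stage
        and (ontogenetic_rank is None or u.ontogenetic_rank == ontogenetic_rank)
    ]
    if not cands:
        raise KeyError(f"no semataphont of taxon {taxon!r} at decay stage {decay_stage}")
    src = cands[0]
    states = matrix.row(src.unit_id).copy()

    source_semaphoronts = [
        u
        for u in matrix.units
        if u.unit_class == "semaphoront"
        and u.taxon == taxon
        and u.ontogenetic_rank == src.ontogenetic_rank
    ]
    if source_semaphoronts:
        undecayed = matrix.row(source_semaphoronts[0].unit_id)
        lost = (undecayed == 1.0) & (states == 0.0)
        states[lost] = np.nan

    rng = np.random.default_rng(seed)
    known = np.flatnonzero(~np.isnan(states))
    n_obscure = int(round(obscure_fraction * known.size))
    if n_obscure:
        states[rng.choice(known, size=n_obscure, replace=False)] = np.nan

    rec = UnitRecord(
        unit_id=f"fossil_{taxon}_d{decay_stage}_s{seed}",
        taxon=taxon,
        unit_class="fossil_specimen",
        ontogenetic_rank=None,
        decay_stage=None,
        label=f"synthetic fossil from {taxon} decay stage {decay_stage}",
    )
    return rec, states


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def load_framework_config(path) -> FrameworkConfig:
    """Load a FrameworkConfig from a YAML file."""
    data = yaml.safe_load(Path(path).read_text())
    taxa = None
    if "taxa" in data:
        taxa = [TaxonConfig(**t) for t in data.pop("taxa")]
    fossils = [FossilGroupConfig(**f) for f in data.pop("fossils", [])]
    cfg = FrameworkConfig(taxa=taxa, fossils=fossils, **data)
    if taxa is not None:
        cfg.n_taxa = len(taxa)
    return cfg


def table1_config(seed: int = 0) -> FrameworkConfig:
    """The checked-in framework census fixture (111 units)."""
    path = Path(__file__).parent / "data" / "table1.yaml"
    cfg = load_framework_config(path)
    cfg.seed = seed
    return cfg
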