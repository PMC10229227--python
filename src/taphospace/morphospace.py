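"""Morphospace analyses over the ordinated framework.

These operations quantify the patterns the ordination is meant to reveal:
stage-ordered trajectories (the dotted decay paths and solid ontogenetic
paths connecting units of one taxon), the convergence of decayed units
from different taxa toward a common region (stem-ward slippage), alignment
of configurations across runs (rotation/reflection are gauge freedoms of
NMDS), and nearest-neighbor placement of fossil specimens against the
extant framework.

Convergence and placement are defined in Gower space by default: the
slippage claim is about morphology, and full dissimilarities avoid the
projection distortion of a 2-D ordination.  Ordination-space variants are
available for plotting parity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix
from .matrix import CharacterMatrix, UnitRecord

__all__ = [
    "Trajectory",
    "ConvergenceProfile",
    "AlignmentReport",
    "FossilPlacement",
    "PlacementReport",
    "SlippageZone",
    "build_trajectories",
    "convergence_profile",
    "align_configurations",
    "place_fossils",
    "slippage_zone",
]

Space = Union[DissimilarityMatrix, pd.DataFrame]


def _pair_distance(space: Space, a: str, b: str) -> float:
    if isinstance(space, DissimilarityMatrix):
        return space.between(a, b)
    va = space.loc[a].to_numpy(dtype=float)
    vb = space.loc[b].to_numpy(dtype=float)
    return float(np.linalg.norm(va - vb))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """A stage-ordered path through one taxon's units."""

    taxon: str
    axis: str  # "decay" or "ontogeny"
    unit_ids: list[str]
    stages: list[int]
    segment_lengths: list[float]
    total_length: float
    space: str  # "gower" or "ordination"
    series_key: tuple = ()  # (taxon, source ontogenetic rank) for decay paths


def build_trajectories(
    space_data: Space,
    matrix: CharacterMatrix,
    axis: str = "decay",
    space: str = "gower",
) -> list[Trajectory]:
    """Connect each taxon's staged units in stage order.

    For the decay axis, units are grouped per (taxon, source ontogenetic
    rank) — a taxon whose adult and larva were both decayed yields two
    paths.  For the ontogeny axis, semaphoronts are ordered by rank.
    Groups with fewer than two staged units emit no trajectory.
    """
    if axis not in ("decay", "ontogeny"):
        raise ValueError(f"unknown axis {axis!r}")
    if space not in ("gower", "ordination"):
        raise ValueError(f"unknown space {space!r}")

    groups: dict[tuple, list[tuple[int, UnitRecord]]] = {}
    for u in matrix.units:
        if axis == "decay":
            if u.unit_class in ("semaphoront", "semataphont") and u.decay_stage is not None:
                groups.setdefault((u.taxon, u.ontogenetic_rank), []).append((u.decay_stage, u))
        else:
            if u.unit_class == "semaphoront" and u.ontogenetic_rank is not None:
                groups.setdefault((u.taxon,), []).append((u.ontogenetic_rank, u))

    if not groups:
        raise ValueError(f"no units carry {axis}-axis stage metadata")

    out: list[Trajectory] = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        members = sorted(groups[key], key=lambda t: (t[0], t[1].unit_id))
        if len(members) < 2:
            continue
        stages = [s for s, _ in members]
        if len(set(stages)) != len(stages):
            raise ValueError(f"duplicate {axis} stages in series {key}: {stages}")
        ids = [u.unit_id for _, u in members]
        seglens = [_pair_distance(space_data, a, b) for a, b in zip(ids, ids[1:])]
        out.append(
            Trajectory(
                taxon=key[0],
                axis=axis,
                unit_ids=ids,
                stages=stages,
                segment_lengths=seglens,
                total_length=float(sum(seglens)),
                space=space,
                series_key=key,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Convergence (stem-ward slippage statistic)
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceProfile:
    """Per decay stage s: mean pairwise Gower dissimilarity C(s) among
    semataphonts of stage s drawn from distinct taxa."""

    stages: list[int]
    values: list[float]
    n_pairs: list[int]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.stages, self.values))

    def is_non_increasing(self, tol: float = 0.0) -> bool:
        return all(b <= a + tol for a, b in zip(self.values, self.values[1:]))


def convergence_profile(D: DissimilarityMatrix, matrix: CharacterMatrix) -> ConvergenceProfile:
    """Inter-taxon dispersion of semataphonts per decay stage.

    Stages represented by fewer than two distinct taxa are omitted with a
    warning; an error is raised when no stage qualifies.
    """
    by_stage: dict[int, list[UnitRecord]] = {}
    for u in matrix.units:
        if u.unit_class == "semataphont" and u.decay_stage is not None and u.decay_stage >= 1:
            by_stage.setdefault(u.decay_stage, []).append(u)

    stages, values, npairs = [], [], []
    for s in sorted(by_stage):
        units = by_stage[s]
        taxa = {u.taxon for u in units}
        if len(taxa) < 2:
            warnings.warn(f"decay stage {s} represented by fewer than 2 taxa; omitted", stacklevel=2)
            continue
        dists = [
            D.between(a.unit_id, b.unit_id)
            for a, b in combinations(units, 2)
            if a.taxon != b.taxon
        ]
        dists = [d for d in dists if not np.isnan(d)]
        if not dists:
            warnings.warn(f"decay stage {s} has no comparable inter-taxon pairs; omitted", stacklevel=2)
            continue
        stages.append(s)
        values.append(float(np.mean(dists)))
        npairs.append(len(dists))
    if not stages:
        raise ValueError("no decay stage is represented by semataphonts of >= 2 taxa")
    return ConvergenceProfile(stages=stages, values=values, n_pairs=npairs)


# ---------------------------------------------------------------------------
# Configuration alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    rotation: np.ndarray
    reflection: bool
    translation: np.ndarray
    scale: float
    rms: float
    rotation_angle: Optional[float] = None  # radians, 2-D only


def align_configurations(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    shared_unit_ids: Optional[list[str]] = None,
    allow_scaling: bool = False,
) -> tuple[pd.DataFrame, AlignmentReport]:
    """Least-squares orthogonal alignment of one ordination onto another.

    Both configurations are DataFrames indexed by unit_id.  The optimal
    rotation (with reflection permitted — axis inversion is a gauge freedom
    of NMDS) and translation are estimated on the shared units and applied
    to *all* target units.  Scaling is off by default since normalized NMDS
    configurations share a scale.
    """
    if shared_unit_ids is None:
        shared_unit_ids = [u for u in reference.index if u in set(target.index)]
    if len(shared_unit_ids) < 3:
        raise ValueError("alignment requires at least 3 shared units")
    if reference.shape[1] != target.shape[1]:
        raise ValueError("configurations must have equal dimensionality")

    Xr = reference.loc[shared_unit_ids].to_numpy(dtype=float)
    Xt = target.loc[shared_unit_ids].to_numpy(dtype=float)
    mu_r = Xr.mean(axis=0)
    mu_t = Xt.mean(axis=0)
    A = (Xt - mu_t).T @ (Xr - mu_r)
    U, svals, Vt = np.linalg.svd(A)
    R = U @ Vt
    if allow_scaling:
        denom = float(np.sum((Xt - mu_t) ** 2))
        scale = float(svals.sum() / denom) if denom > 0 else 1.0
    else:
        scale = 1.0

    aligned_all = (target.to_numpy(dtype=float) - mu_t) @ R * scale + mu_r
    aligned = pd.DataFrame(aligned_all, index=target.index, columns=reference.columns)

    resid = aligned.loc[shared_unit_ids].to_numpy(dtype=float) - Xr
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    angle = float(np.arctan2(R[0, 1], R[0, 0])) if R.shape == (2, 2) else None
    return aligned, AlignmentReport(
        rotation=R,
        reflection=bool(np.linalg.det(R) < 0),
        translation=mu_r - mu_t,
        scale=scale,
        rms=rms,
        rotation_angle=angle,
    )


# ---------------------------------------------------------------------------
# Fossil placement
# ---------------------------------------------------------------------------


@dataclass
class FossilPlacement:
    fossil_id: str
    neighbors: list[tuple[str, float]]  # (extant unit_id, dissimilarity), sorted
    nearest_taxon: Optional[str]
    nearest_unit_class: Optional[str]
    nearest_ontogenetic_rank: Optional[int]
    nearest_decay_stage: Optional[int]
    unplaceable: bool = False

    @property
    def nearest_unit_id(self) -> Optional[str]:
        return self.neighbors[0][0] if self.neighbors else None


@dataclass
class PlacementReport:
    placements: list[FossilPlacement] = field(default_factory=list)

    def __getitem__(self, fossil_id: str) -> FossilPlacement:
        for p in self.placements:
            if p.fossil_id == fossil_id:
                return p
        raise KeyError(fossil_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.placements:
            for rank, (uid, dist) in enumerate(p.neighbors, start=1):
                rows.append(
                    {"fossil_id": p.fossil_id, "rank": rank, "neighbor_id": uid,
                     "dissimilarity": dist, "unplaceable": p.unplaceable}
                )
            if p.unplaceable:
                rows.append(
                    {"fossil_id": p.fossil_id, "rank": np.nan, "neighbor_id": "UNPLACEABLE",
                     "dissimilarity": np.nan, "unplaceable": True}
                )
        return pd.DataFrame(rows)


def place_fossils(D: DissimilarityMatrix, matrix: CharacterMatrix, k: int = 5) -> PlacementReport:
    """Rank the k nearest extant units for every fossil unit.

    Placement uses the full Gower dissimilarities rather than ordination
    coordinates.  Ties are broken lexicographically by unit_id.  A fossil
    with no comparable characters against any extant unit is reported as
    UNPLACEABLE rather than raising.
    """
    fossil_ids = matrix.fossil_unit_ids()
    extant_ids = matrix.extant_unit_ids()
    if not fossil_ids:
        raise ValueError("matrix contains no fossil units")
    if not extant_ids:
        raise ValueError("matrix contains no extant (semaphoront/semataphont) units")

    report = PlacementReport()
    for fid in fossil_ids:
        pairs = []
        for eid in extant_ids:
            d = D.between(fid, eid)
            if not np.isnan(d):
                pairs.append((d, eid))
        pairs.sort(key=lambda t: (t[0], t[1]))
        if not pairs:
            report.placements.append(
                FossilPlacement(
                    fossil_id=fid, neighbors=[], nearest_taxon=None,
                    nearest_unit_class=None, nearest_ontogenetic_rank=None,
                    nearest_decay_stage=None, unplaceable=True,
                )
            )
            continue
        top = [(eid, float(d)) for d, eid in pairs[:k]]
        nearest = matrix.unit(top[0][0])
        report.placements.append(
            FossilPlacement(
                fossil_id=fid,
                neighbors=top,
                nearest_taxon=nearest.taxon,
                nearest_unit_class=nearest.unit_class,
                nearest_ontogenetic_rank=nearest.ontogenetic_rank,
                nearest_decay_stage=nearest.decay_stage,
            )
        )
    return report


# ---------------------------------------------------------------------------
# Stem-ward slippage zone
# ---------------------------------------------------------------------------


@dataclass
class SlippageZone:
    """The region terminal-stage semataphonts converge to.

    In ordination space the zone center is their centroid; in Gower space a
    centroid is undefined, so the center is the medoid terminal unit.
    """

    space: str
    terminal_unit_ids: list[str]
    center: Union[np.ndarray, str]
    distances: dict[str, float]

    def mean_distance(self, unit_ids: list[str]) -> float:
        vals = [self.distances[u] for u in unit_ids if u in self.distances]
        return float(np.mean(vals)) if vals else float("nan")


def slippage_zone(space_data: Space, matrix: CharacterMatrix) -> SlippageZone:
    """Locate the convergence zone and measure every unit's distance to it.

    Terminal stage = the maximum decay stage present per taxon; at least
    two taxa must contribute a terminal semataphont.
    """
    terminal: list[str] = []
    by_taxon: dict[str, list[UnitRecord]] = {}
    for u in matrix.units:
        if u.unit_class == "semataphont" and u.decay_stage is not None and u.decay_stage >= 1:
            by_taxon.setdefault(u.taxon, []).append(u)
    for taxon, units in by_taxon.items():
        smax = max(u.decay_stage for u in units)
        terminal.extend(sorted(u.unit_id for u in units if u.decay_stage == smax))
    if len({matrix.unit(t).taxon for t in terminal}) < 2:
        raise ValueError("slippage zone requires terminal semataphonts from >= 2 taxa")

    if isinstance(space_data, DissimilarityMatrix):
        # medoid terminal unit: minimal summed dissimilarity to the others
        def score(t: str) -> float:
            return float(np.nansum([space_data.between(t, o) for o in terminal if o != t]))

        medoid = min(terminal, key=lambda t: (score(t), t))
        distances = {
            u.unit_id: space_data.between(u.unit_id, medoid) for u in matrix.units
        }
        return SlippageZone(space="gower", terminal_unit_ids=terminal, center=medoid, distances=distances)

    coords = space_data
    centroid = coords.loc[terminal].to_numpy(dtype=float).mean(axis=0)
    distances = {
        str(uid): float(np.linalg.norm(coords.loc[uid].to_numpy(dtype=float) - centroid))
        for uid in coords.index
    }
    return SlippageZone(space="ordination", terminal_unit_ids=terminal, center=centroid, distances=distances)
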