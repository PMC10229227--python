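"""End-to-end pipeline: matrix -> recode -> Gower -> ordination -> analyses.

One call writes every stage's artifact (recoded matrix, distance matrix,
comparable counts, ordination scores, Shepard data, trajectories, fossil
placements, slippage zone) into an output directory plus a JSON manifest
recording parameters, seed and summaries, sufficient to re-run the whole
thing bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._version import __version__
from .dissimilarity import comparable_counts, gower
from .matrix import CharacterMatrix, apply_coding_style, validate
from .matrix_io import read_nexus, read_table, write_nexus
from .morphospace import build_trajectories, convergence_profile, place_fossils, slippage_zone
from .ordination import nmds, pcoa

log = logging.getLogger("taphospace")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    input_path: Optional[str] = None  # NEXUS or CSV/TSV; None with `matrix` passed directly
    coding_style: int = 1
    methods: list[str] = field(default_factory=lambda: ["nmds", "pcoa"])
    k: int = 2
    n_starts: int = 20
    seed: Optional[int] = None
    correction: str = "cailliez"
    output_dir: str = "taphospace_out"
    placement_k: int = 5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if "nmds" in self.methods and self.seed is None:
            raise ValueError("a seed is mandatory when the stochastic NMDS step is requested")
        for m in self.methods:
            if m not in ("nmds", "pcoa"):
                raise ValueError(f"unknown ordination method {m!r}")


def _load(config: PipelineConfig) -> CharacterMatrix:
    p = str(config.input_path)
    if p.endswith((".nex", ".nexus")):
        return read_nexus(p)
    dialect = "tsv" if p.endswith((".tsv", ".tab")) else "csv"
    return read_table(p, dialect=dialect)


def _scores_frame(unit_ids, coords, prefix: str) -> pd.DataFrame:
    cols = [f"{prefix}{i + 1}" for i in range(coords.shape[1])]
    df = pd.DataFrame(coords, index=unit_ids, columns=cols)
    df.index.name = "unit_id"
    return df


def run_pipeline(config: PipelineConfig, matrix: Optional[CharacterMatrix] = None) -> dict:
    """Run the full analysis and return the manifest (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "files": {},
        "summaries": {},
        "warnings": [],
    }

    if matrix is None:
        matrix = _load(config)
    report = validate(matrix)
    if not report.is_valid:
        raise ValueError(f"input matrix invalid: {report.errors}")
    manifest["summaries"]["census"] = report.counts

    recoded = apply_coding_style(matrix, config.coding_style)
    write_nexus(recoded, out / "matrix_recoded.nex")
    manifest["files"]["matrix_recoded"] = "matrix_recoded.nex"
    log.info("coding style %s applied (default style 1 leaves the matrix unchanged)",
             config.coding_style)

    D = gower(recoded, na_policy="error")
    D.to_frame().to_csv(out / "gower.csv")
    counts = comparable_counts(recoded)
    pd.DataFrame(counts, index=D.unit_ids, columns=D.unit_ids).to_csv(out / "comparable_counts.csv")
    manifest["files"]["gower"] = "gower.csv"
    manifest["files"]["comparable_counts"] = "comparable_counts.csv"

    scores: dict[str, pd.DataFrame] = {}
    if "nmds" in config.methods:
        res = nmds(D, k=config.k, n_starts=config.n_starts, seed=config.seed)
        df = _scores_frame(D.unit_ids, res.coordinates, "NMDS")
        df.to_csv(out / "nmds_scores.csv")
        shep = pd.DataFrame(
            {
                "unit_i": [D.unit_ids[i] for i, _ in res.shepard.pair_indices],
                "unit_j": [D.unit_ids[j] for _, j in res.shepard.pair_indices],
                "observed": res.shepard.observed,
                "distance": res.shepard.distances,
                "fitted": res.shepard.fitted,
            }
        )
        shep.to_csv(out / "shepard.csv", index=False)
        manifest["files"]["nmds_scores"] = "nmds_scores.csv"
        manifest["files"]["shepard"] = "shepard.csv"
        manifest["summaries"]["nmds"] = {
            "stress": res.stress,
            "k": res.k,
            "n_starts": res.n_starts,
            "best_start_index": res.best_start_index,
            "all_stresses": res.all_stresses,
            "seed": config.seed,
        }
        scores["nmds"] = df
    if "pcoa" in config.methods:
        res_p = pcoa(D, correction=config.correction)
        df = _scores_frame(D.unit_ids, res_p.coordinates, "PCo")
        df.to_csv(out / "pcoa_scores.csv")
        eig = pd.DataFrame(
            {
                "eigenvalue": res_p.eigenvalues,
                "proportion_explained": np.concatenate(
                    [res_p.proportion_explained,
                     np.full(len(res_p.eigenvalues) - len(res_p.proportion_explained), np.nan)]
                ),
            }
        )
        eig.to_csv(out / "pcoa_eigenvalues.csv", index=False)
        manifest["files"]["pcoa_scores"] = "pcoa_scores.csv"
        manifest["files"]["pcoa_eigenvalues"] = "pcoa_eigenvalues.csv"
        manifest["summaries"]["pcoa"] = {
            "cailliez_constant": res_p.cailliez_constant,
            "n_positive_eigenvalues": int(len(res_p.proportion_explained)),
            "proportion_explained_first2": [float(x) for x in res_p.proportion_explained[:2]],
        }
        scores["pcoa"] = df

    # morphospace analyses run in Gower space; skip gracefully when the
    # metadata needed for a stage is absent
    try:
        trajs = build_trajectories(D, recoded, axis="decay", space="gower")
        rows = [
            {"taxon": t.taxon, "axis": t.axis, "series": "/".join(map(str, t.series_key)),
             "unit_ids": ";".join(t.unit_ids), "total_length": t.total_length}
            for t in trajs
        ]
        pd.DataFrame(rows).to_csv(out / "trajectories_decay.csv", index=False)
        manifest["files"]["trajectories_decay"] = "trajectories_decay.csv"
    except ValueError as e:
        manifest["warnings"].append(f"trajectories skipped: {e}")

    try:
        prof = convergence_profile(D, recoded)
        pd.DataFrame(
            {"decay_stage": prof.stages, "mean_intertaxon_gower": prof.values, "n_pairs": prof.n_pairs}
        ).to_csv(out / "convergence_profile.csv", index=False)
        manifest["files"]["convergence_profile"] = "convergence_profile.csv"
        manifest["summaries"]["convergence"] = prof.as_dict()
    except ValueError as e:
        manifest["warnings"].append(f"convergence profile skipped: {e}")

    try:
        zone = slippage_zone(D, recoded)
        pd.DataFrame(
            {"unit_id": list(zone.distances), "distance_to_zone": list(zone.distances.values())}
        ).to_csv(out / "slippage_zone.csv", index=False)
        manifest["files"]["slippage_zone"] = "slippage_zone.csv"
        manifest["summaries"]["slippage_zone_center"] = (
            zone.center if isinstance(zone.center, str) else [float(x) for x in zone.center]
        )
    except ValueError as e:
        manifest["warnings"].append(f"slippage zone skipped: {e}")

    if recoded.fossil_unit_ids():
        placement = place_fossils(D, recoded, k=config.placement_k)
        placement.to_frame().to_csv(out / "placement.csv", index=False)
        manifest["files"]["placement"] = "placement.csv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["files"]["manifest"] = "manifest.json"
    return manifest
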