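"""Trajectories, convergence, alignment, fossil placement, slippage zone."""

import numpy as np
import pandas as pd
import pytest

from taphospace.dissimilarity import gower
from taphospace.matrix import CharacterMatrix, UnitRecord, apply_coding_style
from taphospace.morphospace import (
    align_configurations,
    build_trajectories,
    convergence_profile,
    place_fossils,
    slippage_zone,
)
from taphospace.staging import (
    FrameworkConfig,
    make_synthetic_fossil,
    simulate_framework,
)

from conftest import gower_oracle


def _staged_matrix():
    """One taxon with decay stages listed out of order, plus a second taxon
    with a single staged unit."""
    states = np.array(
        [[1, 1, 1], [0, 1, 1], [0, 0, 1], [1, 1, 0], [1, 0, 0]], dtype=float
    )
    units = [
        UnitRecord("a1", taxon="A", unit_class="semataphont", decay_stage=1),
        UnitRecord("a3", taxon="A", unit_class="semataphont", decay_stage=3),
        UnitRecord("a2", taxon="A", unit_class="semataphont", decay_stage=2),
        UnitRecord("b1", taxon="B", unit_class="semataphont", decay_stage=1),
        UnitRecord("f", taxon="", unit_class="fossil_specimen"),
    ]
    return CharacterMatrix(characters=["c1", "c2", "c3"], units=units, states=states)


class TestTrajectories:
    def test_out_of_order_stages_sorted(self):
        m = _staged_matrix()
        D = gower(m)
        trajs = build_trajectories(D, m, axis="decay", space="gower")
        (t,) = trajs  # taxon B has one staged unit -> no trajectory
        assert t.taxon == "A"
        assert t.stages == [1, 2, 3]
        assert t.unit_ids == ["a1", "a2", "a3"]

    def test_segment_lengths_match_oracle(self, default_framework):
        m = default_framework.matrix
        D = gower(m)
        oracle = gower_oracle(m.states)
        ids = m.unit_ids
        for t in build_trajectories(D, m, axis="decay", space="gower"):
            for (a, b), seg in zip(zip(t.unit_ids, t.unit_ids[1:]), t.segment_lengths):
                assert seg == pytest.approx(oracle[ids.index(a), ids.index(b)], abs=1e-12)
            assert t.total_length == pytest.approx(sum(t.segment_lengths))

    def test_ontogeny_axis_uses_semaphoronts(self, default_framework):
        m = default_framework.matrix
        D = gower(m)
        trajs = build_trajectories(D, m, axis="ontogeny", space="gower")
        assert len(trajs) == 4  # one per simulated taxon
        for t in trajs:
            assert t.stages == sorted(t.stages)
            for uid in t.unit_ids:
                assert m.unit(uid).unit_class == "semaphoront"

    def test_missing_axis_metadata_rejected(self):
        m = CharacterMatrix(
            characters=["c"],
            units=[UnitRecord("f1"), UnitRecord("f2")],
            states=np.array([[1.0], [0.0]]),
        )
        with pytest.raises(ValueError, match="stage metadata"):
            build_trajectories(gower(m), m, axis="decay")


class TestConvergenceProfile:
    def test_identical_taxa_give_zero(self):
        states = np.array([[1, 0], [1, 0], [0, 0], [0, 0]], dtype=float)
        units = [
            UnitRecord("a1", taxon="A", unit_class="semataphont", decay_stage=1),
            UnitRecord("b1", taxon="B", unit_class="semataphont", decay_stage=1),
            UnitRecord("a2", taxon="A", unit_class="semataphont", decay_stage=2),
            UnitRecord("b2", taxon="B", unit_class="semataphont", decay_stage=2),
        ]
        m = CharacterMatrix(characters=["c1", "c2"], units=units, states=states)
        prof = convergence_profile(gower(m), m)
        assert prof.values == [0.0, 0.0]

    def test_resistant_last_regime_is_non_increasing(self, default_framework):
        m = default_framework.matrix
        prof = convergence_profile(gower(m), m)
        assert prof.stages == [1, 2, 3, 4, 5, 6]
        assert prof.is_non_increasing()
        assert all(0 <= v <= 1 for v in prof.values)

    def test_labile_last_regime_runs_without_monotonicity_claim(self):
        fw = simulate_framework(FrameworkConfig(seed=1, retention_rule="labile_last"))
        prof = convergence_profile(gower(fw.matrix), fw.matrix)
        assert len(prof.values) == 6  # regime difference: no monotone assertion

    def test_single_taxon_stage_omitted_with_warning(self):
        states = np.array([[1, 0], [0, 1], [0, 0]], dtype=float)
        units = [
            UnitRecord("a1", taxon="A", unit_class="semataphont", decay_stage=1),
            UnitRecord("b1", taxon="B", unit_class="semataphont", decay_stage=1),
            UnitRecord("a2", taxon="A", unit_class="semataphont", decay_stage=2),
        ]
        m = CharacterMatrix(characters=["c1", "c2"], units=units, states=states)
        with pytest.warns(UserWarning, match="fewer than 2 taxa"):
            prof = convergence_profile(gower(m), m)
        assert prof.stages == [1]

    def test_no_qualifying_stage_is_error(self):
        states = np.array([[1, 0], [0, 1]], dtype=float)
        units = [
            UnitRecord("a1", taxon="A", unit_class="semataphont", decay_stage=1),
            UnitRecord("a2", taxon="A", unit_class="semataphont", decay_stage=2),
        ]
        m = CharacterMatrix(characters=["c1", "c2"], units=units, states=states)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                convergence_profile(gower(m), m)


class TestAlignment:
    @staticmethod
    def _frame(X):
        return pd.DataFrame(X, index=[f"u{i}" for i in range(len(X))])

    def test_axis_negation_recovered_and_flagged(self):
        rng = np.random.default_rng(1)
        ref = self._frame(rng.normal(size=(8, 2)))
        target = ref.copy()
        target[1] = -target[1]
        aligned, rep = align_configurations(ref, target)
        assert rep.reflection
        assert rep.rms <= 1e-10
        assert np.allclose(aligned.to_numpy(), ref.to_numpy(), atol=1e-10)

    def test_rotation_recovered_with_angle(self):
        rng = np.random.default_rng(2)
        ref = self._frame(rng.normal(size=(6, 2)))
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        target = self._frame(ref.to_numpy() @ R)
        aligned, rep = align_configurations(ref, target)
        assert rep.rms <= 1e-10
        assert not rep.reflection
        assert abs(abs(rep.rotation_angle) - theta) <= 1e-10

    def test_noise_perturbation_residual_within_bounds(self):
        rng = np.random.default_rng(3)
        sigma = 0.01
        ref = self._frame(rng.normal(size=(30, 2)))
        target = self._frame(ref.to_numpy() + rng.normal(scale=sigma, size=(30, 2)))
        _, rep = align_configurations(ref, target)
        assert rep.rms <= 3 * sigma * np.sqrt(2)
        assert rep.rms > 0

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        ref = self._frame(rng.normal(size=(7, 3)))
        target = self._frame(rng.normal(size=(7, 3)))
        once, _ = align_configurations(ref, target)
        twice, _ = align_configurations(ref, once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_applies_to_non_shared_units(self):
        rng = np.random.default_rng(5)
        ref = self._frame(rng.normal(size=(5, 2)))
        extra = pd.DataFrame(rng.normal(size=(2, 2)), index=["x1", "x2"])
        target = pd.concat([-ref, extra])  # point reflection of everything
        aligned, rep = align_configurations(ref, target, shared_unit_ids=list(ref.index))
        assert np.allclose(aligned.loc[ref.index].to_numpy(), ref.to_numpy(), atol=1e-10)
        assert np.allclose(aligned.loc[["x1", "x2"]].to_numpy(), -extra.to_numpy(), atol=1e-10)

    def test_too_few_shared_units(self):
        rng = np.random.default_rng(6)
        ref = self._frame(rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="3 shared"):
            align_configurations(ref, ref.copy())


class TestPlacement:
    def test_identical_fossil_at_distance_zero(self, default_framework):
        m = default_framework.matrix.copy()
        target = next(u for u in m.units if u.unit_class == "semataphont")
        m.append_unit(
            UnitRecord("fossil_twin", taxon="", unit_class="fossil_specimen"),
            m.row(target.unit_id).copy(),
        )
        D = gower(m)
        report = place_fossils(D, m, k=3)
        p = report["fossil_twin"]
        assert p.neighbors[0][1] == 0.0
        assert p.nearest_taxon == target.taxon

    def test_synthetic_fossil_recovers_source_under_strict_coding(self, default_framework):
        """Under tolerant (style-1) coding a fossil's decay losses are '?'
        and drop out of every comparison, leaving it equidistant (0) from
        its source semataphont and all less-decayed units of the same rank.
        Only strict (style-2) recoding makes the losses informative, so
        stage recovery is tested on the recoded matrix."""
        fw = default_framework
        m = fw.matrix.copy()
        taxon = fw.config.resolved_taxa()[1].name
        rec, states = make_synthetic_fossil(m, taxon, decay_stage=3, obscure_fraction=0.1, seed=5)
        m.append_unit(rec, states)
        D1 = gower(m, na_policy="allow")
        p1 = place_fossils(D1, m, k=5)[rec.unit_id]
        assert p1.nearest_taxon == taxon  # taxon recovered even under style 1
        assert p1.neighbors[0][1] == 0.0

        m2 = apply_coding_style(m, 2)
        D2 = gower(m2)
        p2 = place_fossils(D2, m2, k=5)[rec.unit_id]
        assert p2.nearest_taxon == taxon
        assert p2.nearest_decay_stage == 3

    def test_ranking_matches_oracle_sort(self, default_framework):
        fw = default_framework
        m = fw.matrix.copy()
        rec, states = make_synthetic_fossil(
            m, fw.config.resolved_taxa()[0].name, decay_stage=2, obscure_fraction=0.3, seed=9
        )
        m.append_unit(rec, states)
        D = gower(m, na_policy="allow")
        report = place_fossils(D, m, k=10)
        oracle = gower_oracle(m.states)
        fi = m.unit_index(rec.unit_id)
        expected = sorted(
            ((oracle[fi, m.unit_index(e)], e) for e in m.extant_unit_ids()),
            key=lambda t: (t[0], t[1]),
        )[:10]
        assert [(e, pytest.approx(d)) for d, e in expected] == report[rec.unit_id].neighbors

    def test_unplaceable_fossil_reported_not_raised(self, tiny_matrix):
        m = tiny_matrix.copy()
        m.append_unit(
            UnitRecord("blank", taxon="", unit_class="fossil_specimen"),
            np.full(4, np.nan),
        )
        D = gower(m, na_policy="allow")
        report = place_fossils(D, m, k=2)
        assert report["blank"].unplaceable
        df = report.to_frame()
        assert "UNPLACEABLE" in df["neighbor_id"].values


class TestSlippageZone:
    def test_identical_terminals_have_zero_dispersion(self):
        states = np.array([[1, 1], [0, 0], [1, 0], [0, 0]], dtype=float)
        units = [
            UnitRecord("a1", taxon="A", unit_class="semataphont", decay_stage=1),
            UnitRecord("a2", taxon="A", unit_class="semataphont", decay_stage=2),
            UnitRecord("b1", taxon="B", unit_class="semataphont", decay_stage=1),
            UnitRecord("b2", taxon="B", unit_class="semataphont", decay_stage=2),
        ]
        m = CharacterMatrix(characters=["c1", "c2"], units=units, states=states)
        zone = slippage_zone(gower(m), m)
        assert set(zone.terminal_unit_ids) == {"a2", "b2"}
        assert zone.mean_distance(zone.terminal_unit_ids) == 0.0

    def test_mean_distance_decreases_with_decay_stage(self, default_framework):
        m = default_framework.matrix
        D = gower(m)
        zone = slippage_zone(D, m)
        by_stage = {}
        for u in m.units:
            if u.unit_class == "semataphont":
                by_stage.setdefault(u.decay_stage, []).append(u.unit_id)
        means = [zone.mean_distance(by_stage[s]) for s in sorted(by_stage)]
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_plesiomorphic_proxy_lies_inside_zone(self, default_framework):
        """A unit carrying only the shared decay-resistant characters (an
        ancestral-proxy morphology) sits within the convergence zone."""
        fw = default_framework
        m = fw.matrix.copy()
        proxy = np.zeros(m.n_characters)
        for c in fw.shared_resistant:
            proxy[m.characters.index(c)] = 1.0
        m.append_unit(UnitRecord("proxy", taxon="proxy", unit_class="fossil_specimen"), proxy)
        D = gower(m)
        zone = slippage_zone(D, m)
        S = fw.config.n_decay_stages
        terminal_mean = zone.mean_distance(zone.terminal_unit_ids)
        assert zone.distances["proxy"] <= max(terminal_mean, 1e-12)

    def test_ordination_space_uses_centroid(self, default_framework):
        m = default_framework.matrix
        D = gower(m)
        from taphospace.ordination import nmds

        res = nmds(D, k=2, n_starts=3, seed=2)
        coords = pd.DataFrame(res.coordinates, index=D.unit_ids)
        zone = slippage_zone(coords, m)
        assert zone.space == "ordination"
        assert isinstance(zone.center, np.ndarray)
        assert len(zone.distances) == m.n_units

    def test_requires_two_taxa(self):
        states = np.array([[1, 0], [0, 0]], dtype=float)
        units = [
            UnitRecord("a1", taxon="A", unit_class="semataphont", decay_stage=1),
            UnitRecord("a2", taxon="A", unit_class="semataphont", decay_stage=2),
        ]
        m = CharacterMatrix(characters=["c1", "c2"], units=units, states=states)
        with pytest.raises(ValueError, match=">= 2 taxa"):
            slippage_zone(gower(m), m)
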