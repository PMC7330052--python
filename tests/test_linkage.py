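import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from tetragam import sim
from tetragam.inheritance import genotype_probs
from tetragam.linkage import (
    GeneticMap,
    LinkageError,
    LinkageGroupMap,
    PairwiseLinkage,
    build_map,
    estimate_rf,
    group_markers,
    kosambi,
    marey_diagnostics,
    order_markers,
    pairwise_linkage,
    two_locus_probs,
)

from conftest import make_markers


def r_from_kosambi(d_cm: float) -> float:
    x = math.exp(d_cm / 25.0)
    return 0.5 * (x - 1.0) / (x + 1.0)


class TestTwoLocusProbs:
    def test_no_recombination_diagonal(self):
        t = two_locus_probs(0.0)
        np.testing.assert_allclose(np.diag(t), [1 / 6, 2 / 3, 1 / 6])
        assert t.sum() == pytest.approx(1.0)
        off = t - np.diag(np.diag(t))
        assert np.all(off == 0.0)

    def test_independence_limit(self):
        t = two_locus_probs(0.5)
        # heterogenetic configs contribute (1/4)^2 each with weight 2/3
        assert t[0, 0] == pytest.approx(1 / 24)
        # 1/3 + (2/3) * (1/4)
        assert t[1, 1] == pytest.approx(1 / 2)

    @pytest.mark.parametrize("r", [0.0, 0.1, 0.25, 0.4, 0.5])
    def test_marginals_equal_single_locus(self, r):
        t = two_locus_probs(r)
        expected = genotype_probs(0.0, 0.0)
        np.testing.assert_allclose(t.sum(axis=1), expected)
        np.testing.assert_allclose(t.sum(axis=0), expected)

    @pytest.mark.parametrize("r", [0.0, 0.3, 0.5])
    def test_symmetric_under_allele_swap(self, r):
        t = two_locus_probs(r)
        np.testing.assert_allclose(t, t[::-1, ::-1])

    def test_out_of_range(self):
        with pytest.raises(LinkageError):
            two_locus_probs(0.6)


class TestEstimateRf:
    def test_recovers_generating_value(self):
        counts = 6000 * two_locus_probs(0.2)
        pl = estimate_rf(counts)
        assert pl.r_hat == pytest.approx(0.2, abs=0.01)

    def test_independence(self):
        counts = 6000 * two_locus_probs(0.5)
        pl = estimate_rf(counts)
        assert pl.r_hat == pytest.approx(0.5, abs=1e-4)
        assert pl.lod == pytest.approx(0.0, abs=1e-6)

    def test_perfect_cosegregation(self):
        counts = np.diag([200 * p for p in (1 / 6, 2 / 3, 1 / 6)])
        pl = estimate_rf(counts)
        assert pl.r_hat == pytest.approx(0.0, abs=1e-6)
        assert pl.lod > 3.0

    def test_degenerate_flag(self):
        counts = np.zeros((3, 3))
        counts[1, 1] = 50
        pl = estimate_rf(counts)
        assert pl.degenerate

    def test_empty_error(self):
        with pytest.raises(LinkageError):
            estimate_rf(np.zeros((3, 3)))


class TestKosambi:
    @pytest.mark.parametrize(
        "r,expected", [(0.0, 0.0), (0.1, 10.14), (0.25, 27.47)]
    )
    def test_closed_form(self, r, expected):
        assert kosambi(r) == pytest.approx(expected, abs=0.01)

    def test_monotone_and_convex(self):
        rs = np.linspace(0.0, 0.49, 200)
        ds = np.array([kosambi(r) for r in rs])
        diffs = np.diff(ds)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) > 0)

    def test_out_of_range(self):
        with pytest.raises(LinkageError):
            kosambi(0.5)


def _pl(a, b, r, lod):
    return PairwiseLinkage(a, b, r, lod, 100, lod_independence=lod)


class TestGroupMarkers:
    def test_two_blocks(self):
        pw = [
            _pl("a", "b", 0.05, 20),
            _pl("c", "d", 0.05, 20),
            _pl("a", "c", 0.5, 0),
            _pl("a", "d", 0.5, 0),
            _pl("b", "c", 0.5, 0),
            _pl("b", "d", 0.5, 0),
        ]
        groups, unassigned = group_markers(pw, 14, score="lod")
        assert sorted(sorted(g) for g in groups) == [["a", "b"], ["c", "d"]]
        assert unassigned == []

    def test_transitivity(self):
        pw = [
            _pl("a", "b", 0.1, 15),
            _pl("b", "c", 0.1, 15),
            _pl("a", "c", 0.3, 2),
        ]
        groups, _ = group_markers(pw, 14, score="lod")
        assert len(groups) == 1 and sorted(groups[0]) == ["a", "b", "c"]

    def test_singleton_unassigned(self):
        pw = [
            _pl("a", "b", 0.05, 20),
            _pl("a", "x", 0.5, 1),
            _pl("b", "x", 0.5, 1),
        ]
        groups, unassigned = group_markers(pw, 14, score="lod")
        assert unassigned == ["x"]


class TestOrderMarkers:
    def test_three_collinear(self):
        pw = [
            _pl("a", "b", r_from_kosambi(5), 20),
            _pl("b", "c", r_from_kosambi(5), 20),
            _pl("a", "c", r_from_kosambi(10), 20),
        ]
        meta = {m.marker_id: m for m in make_markers(3)}
        ids = list(meta)
        pw = [
            _pl(ids[0], ids[1], r_from_kosambi(5), 20),
            _pl(ids[1], ids[2], r_from_kosambi(5), 20),
            _pl(ids[0], ids[2], r_from_kosambi(10), 20),
        ]
        ordered, pos = order_markers(ids, pw, meta)
        assert ordered == ids  # oriented by bp
        np.testing.assert_allclose(pos, [0.0, 5.0, 10.0], atol=1e-9)

    def test_two_markers(self):
        meta = {m.marker_id: m for m in make_markers(2)}
        ids = list(meta)
        pw = [_pl(ids[1], ids[0], r_from_kosambi(7), 20)]
        ordered, pos = order_markers(ids, pw, meta)
        assert ordered == ids
        assert pos[1] == pytest.approx(7.0, abs=1e-6)

    def test_simulated_chromosome_order_recovery(self):
        cfg = sim.SimConfig(
            chromosomes=[sim.make_chromosome("1", 15, 100.0, 15_000_000, pp=0.7)],
            n_gametes=250,
            seed=12,
            mode="chromosome_wise",
        )
        g, _ = sim.simulate_chromosome_wise(cfg)
        pw = pairwise_linkage(g)
        meta = {m.marker_id: m for m in g.markers}
        ordered, _ = order_markers(g.marker_ids, pw, meta)
        true_rank = {m: k for k, m in enumerate(g.marker_ids)}
        rho = spearmanr([true_rank[m] for m in ordered], range(len(ordered)))[0]
        assert abs(rho) >= 0.95

    def test_map_length_invariant_to_label_permutation(self, rng):
        cfg = sim.SimConfig(
            chromosomes=[sim.make_chromosome("1", 10, 60.0, 10_000_000, pp=0.0)],
            n_gametes=2000,
            seed=3,
            mode="chromosome_wise",
        )
        g, _ = sim.simulate_chromosome_wise(cfg)
        pw = pairwise_linkage(g)
        meta = {m.marker_id: m for m in g.markers}
        _, pos1 = order_markers(g.marker_ids, pw, meta)
        shuffled = list(g.marker_ids)
        rng.shuffle(shuffled)
        _, pos2 = order_markers(shuffled, pw, meta)
        assert pos1[-1] == pytest.approx(pos2[-1], rel=1e-6)


class TestMareyDiagnostics:
    def _map_from(self, marker_ids, positions):
        return GeneticMap(
            groups=[
                LinkageGroupMap("LG1", marker_ids, positions, positions[-1])
            ],
            unassigned=[],
        )

    def test_perfectly_collinear(self):
        markers = {m.marker_id: m for m in make_markers(5)}
        ids = list(markers)
        gmap = self._map_from(ids, [0.0, 2.0, 4.0, 6.0, 8.0])
        per_lg, synteny, marey = marey_diagnostics(gmap, markers)
        assert per_lg.iloc[0]["spearman_rho"] == pytest.approx(1.0)
        assert synteny == 100.0
        assert len(marey) == 5

    def test_intruder_marker_synteny(self):
        markers = {m.marker_id: m for m in make_markers(9)}
        intruder = make_markers(1, chromosome="2", start_bp=5_000_000)[0]
        markers[intruder.marker_id] = intruder
        ids = list(markers)
        gmap = self._map_from(ids, [float(i) for i in range(10)])
        per_lg, synteny, _ = marey_diagnostics(gmap, markers)
        assert per_lg.iloc[0]["synteny_pct"] == pytest.approx(90.0)
        assert synteny == pytest.approx(90.0)

    def test_rate_arithmetic(self):
        # 24.9 cM over 26.32 Mb -> 0.95 cM/Mb
        markers = {
            "a": make_markers(1, start_bp=1)[0],
            "b": make_markers(1, start_bp=26_320_001)[0],
        }
        markers = {
            "a": type(markers["a"])("a", "1", 1, "other"),
            "b": type(markers["b"])("b", "1", 26_320_001, "other"),
        }
        gmap = self._map_from(["a", "b"], [0.0, 24.9])
        per_lg, _, _ = marey_diagnostics(gmap, markers)
        assert per_lg.iloc[0]["rate_cM_per_Mb"] == pytest.approx(0.95, abs=0.005)

    def test_small_group_rho_flagged(self):
        markers = {m.marker_id: m for m in make_markers(2)}
        ids = list(markers)
        gmap = self._map_from(ids, [0.0, 5.0])
        per_lg, _, _ = marey_diagnostics(gmap, markers)
        assert math.isnan(per_lg.iloc[0]["spearman_rho"])


class TestBuildMap:
    def test_two_chromosome_map(self):
        cfg = sim.SimConfig(
            chromosomes=[
                sim.make_chromosome("1", 8, 60.0, 10_000_000, pp=0.4),
                sim.make_chromosome("2", 8, 60.0, 10_000_000, pp=0.4),
            ],
            n_gametes=400,
            seed=21,
            mode="chromosome_wise",
        )
        g, _ = sim.simulate_chromosome_wise(cfg)
        gmap, pw = build_map(g, lod_threshold=5.0)
        assert len(gmap.groups) == 2
        meta = {m.marker_id: m for m in g.markers}
        per_lg, synteny, _ = marey_diagnostics(gmap, meta)
        assert synteny == 100.0
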