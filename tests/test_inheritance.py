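import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetragam import sim
from tetragam.inheritance import (
    BETA_MAX,
    GenotypeCounts,
    ModelError,
    counts_at,
    estimate_chromosome,
    estimate_dr,
    estimate_tau,
    genotype_probs,
    loglik,
    phr_summary,
)

from _oracles import enumerate_single_locus, grid_ml_beta, grid_ml_tau
from conftest import gametes_from_counts


class TestGenotypeProbs:
    def test_full_disomy(self):
        assert genotype_probs(1.0, 0.0) == (0.0, 1.0, 0.0)

    def test_full_tetrasomy_141(self):
        p = genotype_probs(0.0, 0.0)
        assert p == pytest.approx((1 / 6, 2 / 3, 1 / 6))

    def test_max_dr(self):
        # frozen from the enumeration oracle: DR gametes are AA/MM w.p. 1/2
        p = genotype_probs(0.0, 1 / 6)
        assert p == pytest.approx((2 / 9, 5 / 9, 2 / 9))

    @pytest.mark.parametrize("pp", np.linspace(0, 1, 7))
    @pytest.mark.parametrize("beta", [0.0, 0.05, 1 / 6])
    def test_matches_enumeration_oracle(self, pp, beta):
        assert genotype_probs(pp, beta) == pytest.approx(
            enumerate_single_locus(pp, beta), abs=1e-12
        )

    def test_sums_to_one_and_symmetric_on_grid(self):
        for pp in np.linspace(0.0, 1.0, 101):
            for beta in np.linspace(0.0, 1 / 6, 18):
                p_aa, p_am, p_mm = genotype_probs(pp, beta)
                assert p_aa + p_am + p_mm == pytest.approx(1.0)
                assert p_aa == p_mm

    @pytest.mark.parametrize("pp,beta", [(-0.1, 0.0), (1.1, 0.0), (0.5, 0.2), (0.5, -0.01)])
    def test_out_of_range(self, pp, beta):
        with pytest.raises(ModelError):
            genotype_probs(pp, beta)


class TestLoglik:
    def test_all_mass_on_am(self):
        assert loglik(GenotypeCounts(0, 10, 0), 1.0, 0.0) == pytest.approx(0.0)

    def test_impossible_class(self):
        assert loglik(GenotypeCounts(1, 9, 0), 1.0, 0.0) == -math.inf

    def test_direct_arithmetic(self):
        # multinomial(6; 1,4,1) = 30 ways
        expected = math.log(30) + math.log((1 / 6) * (2 / 3) ** 4 * (1 / 6))
        assert loglik(GenotypeCounts(1, 4, 1), 0.0, 0.0) == pytest.approx(expected)


class TestEstimateTau:
    def test_fully_disomic(self):
        tau, se = estimate_tau(GenotypeCounts(0, 300, 0))
        assert tau == 0.0 and se == 0.0

    def test_fully_tetrasomic(self):
        tau, _ = estimate_tau(GenotypeCounts(50, 200, 50))
        assert tau == pytest.approx(1.0)

    def test_intermediate(self):
        tau, _ = estimate_tau(GenotypeCounts(10, 280, 10))
        assert tau == pytest.approx(0.2)

    def test_clipped_to_one(self):
        tau, _ = estimate_tau(GenotypeCounts(40, 10, 40))
        assert tau == 1.0

    def test_zero_counts_error(self):
        with pytest.raises(ModelError):
            estimate_tau(GenotypeCounts(0, 0, 0))

    def test_equals_grid_ml(self, rng):
        counts = rng.multinomial(400, [1 / 8, 3 / 4, 1 / 8], size=100)
        tau_closed = np.array([estimate_tau(GenotypeCounts(*c))[0] for c in counts])
        tau_grid = grid_ml_tau(counts)
        np.testing.assert_allclose(tau_closed, tau_grid, atol=1e-3)


class TestEstimateDr:
    def test_no_excess_homozygosity(self):
        # f_hom = tau/3 exactly => beta = 0
        beta, _ = estimate_dr(GenotypeCounts(10, 280, 10), tau=0.2)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_table_magnitude(self):
        beta, _ = estimate_dr(GenotypeCounts(528, 8944, 528), tau=0.249)
        assert beta == pytest.approx(0.136, abs=5e-4)
        grid = grid_ml_beta(np.array([528, 8944, 528]), tau=0.249)
        assert beta == pytest.approx(grid[0], abs=1e-3)

    def test_clipped_to_max(self):
        # f_hom beyond the admissible maximum tau*(1/3 + 1/9)
        beta, _ = estimate_dr(GenotypeCounts(100, 300, 100), tau=0.6)
        assert beta == pytest.approx(BETA_MAX)

    def test_tau_zero_error(self):
        with pytest.raises(ModelError, match="unidentifiable"):
            estimate_dr(GenotypeCounts(1, 8, 1), tau=0.0)

    def test_equals_grid_ml(self, rng):
        tau = 0.4
        counts = rng.multinomial(500, genotype_probs(1 - tau, 0.08), size=100)
        closed = np.array([estimate_dr(GenotypeCounts(*c), tau)[0] for c in counts])
        grid = grid_ml_beta(counts, tau)
        np.testing.assert_allclose(closed, grid, atol=1e-3)


class TestEstimateChromosome:
    def test_fully_disomic_chromosome(self):
        g = gametes_from_counts(
            [(0, 50, 0)] * 4, roles=["centromeric"] * 4
        )
        est = estimate_chromosome(g, "1")
        assert est.PP == 1.0 and est.PP_sd == 0.0

    def test_tau_averaging(self):
        g = gametes_from_counts(
            [(10, 280, 10), (15, 270, 15)], roles=["centromeric"] * 2
        )
        est = estimate_chromosome(g, "1")
        assert est.tau == pytest.approx(0.25)
        assert est.PP_sd == pytest.approx(0.0707, abs=1e-3)

    def test_no_centromeric_marker_error(self):
        g = gametes_from_counts([(10, 280, 10)], roles=["other"])
        with pytest.raises(ModelError, match="no centromeric"):
            estimate_chromosome(g, "1")

    def test_recovery_at_pp_082(self):
        cfg = sim.SimConfig(
            chromosomes=[sim.make_chromosome("2", 4, 1.0, 4_000, pp=0.82,
                                             n_centromeric=4, n_telomeric_per_arm=0)],
            n_gametes=50_000,
            seed=123,
        )
        g = sim.simulate_locus_wise(cfg)
        est = estimate_chromosome(g, "2")
        assert est.PP == pytest.approx(0.82, abs=0.01)


class TestPhrSummary:
    def test_marker_phr(self):
        g = gametes_from_counts([(1, 3, 0)])
        s = phr_summary(g)
        assert s.per_marker["phr"].iloc[0] == pytest.approx(0.75)

    def test_gamete_phr_ignores_missing(self):
        g = gametes_from_counts([(0, 4, 0), (0, 4, 0), (4, 0, 0)])
        g.genotype[0, 1] = -1  # gamete 0: [AM, missing, AA] -> 1/2
        s = phr_summary(g)
        row = s.per_gamete.set_index("gamete_id").loc["g0"]
        assert row["phr"] == pytest.approx(1 / 2)
        assert row["n_obs"] == 2

    def test_fully_heterozygous_chromosome(self):
        g = gametes_from_counts([(0, 5, 0), (0, 5, 0)])
        s = phr_summary(g)
        chrom = s.per_chromosome.iloc[0]
        assert chrom["phr_mean"] == 1.0
        assert chrom["pct_full_het"] == 100.0
        assert s.genome_mean == 1.0

    def test_chromosome_mean_is_marker_mean(self):
        g = gametes_from_counts([(1, 3, 0), (0, 2, 2), (2, 2, 0)])
        s = phr_summary(g)
        assert s.per_chromosome.iloc[0]["phr_mean"] == pytest.approx(
            s.per_marker["phr"].mean()
        )

    def test_phr_centromeric_identity(self):
        # E[PHR] = 1 - tau/3 at a centromeric locus; check within 3 binomial SE
        pp, n = 0.7, 60_000
        cfg = sim.SimConfig(
            chromosomes=[sim.make_chromosome("1", 1, 1.0, 1000, pp=pp,
                                             n_centromeric=1, n_telomeric_per_arm=0)],
            n_gametes=n,
            seed=99,
        )
        g = sim.simulate_locus_wise(cfg)
        expected = 1 - (1 - pp) / 3
        se = math.sqrt(expected * (1 - expected) / n)
        assert phr_summary(g).genome_mean == pytest.approx(expected, abs=3 * se)


class TestConsistency:
    @pytest.mark.parametrize("pp", [0.633, 0.82, 0.995])
    def test_tau_consistency(self, pp):
        cfg = sim.SimConfig(
            chromosomes=[sim.make_chromosome("1", 1, 1.0, 1000, pp=pp,
                                             n_centromeric=1, n_telomeric_per_arm=0)],
            n_gametes=50_000,
            seed=7,
        )
        g = sim.simulate_locus_wise(cfg)
        tau, _ = estimate_tau(counts_at(g, 0))
        assert tau == pytest.approx(1 - pp, abs=0.01)

    def test_beta_recovery(self):
        tau, beta = 0.3, 0.12
        cfg = sim.SimConfig(
            chromosomes=[
                sim.SimChromosome(
                    chromosome="1",
                    length_cm=100.0,
                    markers=[sim.SimMarker("S1_1", 1, 100.0, "telomeric")],
                    centromere_cm=0.0,
                    pp=1 - tau,
                    beta_telomeric=beta,
                )
            ],
            n_gametes=50_000,
            seed=11,
        )
        g = sim.simulate_locus_wise(cfg)
        beta_hat, _ = estimate_dr(counts_at(g, 0), tau)
        assert beta_hat == pytest.approx(beta, abs=0.02)


@given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
@settings(max_examples=60, deadline=None)
def test_closed_form_tau_matches_grid_property(n_aa, n_am, n_mm):
    if n_aa + n_am + n_mm == 0:
        return
    closed = estimate_tau(GenotypeCounts(n_aa, n_am, n_mm))[0]
    grid = grid_ml_tau(np.array([n_aa, n_am, n_mm]))[0]
    assert closed == pytest.approx(grid, abs=1e-3)
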