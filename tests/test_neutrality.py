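import numpy as np
import pytest

from balscan import neutrality as nt
from balscan.simulate import CoalescentConfig, simulate_sfs_counts
from conftest import make_matrix
from oracles import abh_brute, fuli_brute, pi_locus_brute, random_matrix, seg_sites_brute, tajima_d_brute


class TestDescriptiveStatistics:
    def test_monomorphic_matrix_has_zero_segregating_sites(self):
        assert nt.segregating_sites(make_matrix(np.zeros((5, 6)))) == 0

    def test_two_haplotypes_three_differences(self):
        data = np.zeros((10, 2), dtype=int)
        data[[1, 4, 7], 0] = 1
        assert nt.segregating_sites(make_matrix(data)) == 3

    def test_pi_definition_two_haplotypes(self):
        # k = 4 differences, L = 1000 -> pi = 0.004
        data = np.zeros((4, 2), dtype=int)
        data[:, 0] = 1
        assert nt.nucleotide_diversity(make_matrix(data), 1000) == pytest.approx(0.004)

    def test_pi_zero_for_identical_haplotypes(self):
        assert nt.nucleotide_diversity(make_matrix(np.ones((3, 8)) * 0), 500) == 0.0

    def test_locus_shorter_than_site_count_raises(self):
        with pytest.raises(ValueError, match="locus_length"):
            nt.nucleotide_diversity(make_matrix(np.zeros((10, 4))), 5)

    def test_pi_total_is_integer_conservation(self, rng):
        for _ in range(20):
            data = random_matrix(rng)
            H = make_matrix(data)
            n = H.n_chromosomes
            total = nt.nucleotide_diversity(H, 10_000) * 10_000 * n * (n - 1) / 2
            assert total == pytest.approx(round(total), abs=1e-6)


class TestStatisticOracles:
    """Fast implementations vs brute-force oracles on random fixtures."""

    def test_segregating_sites_matches_brute_force(self, rng):
        for _ in range(100):
            data = random_matrix(rng)
            assert nt.segregating_sites(make_matrix(data)) == seg_sites_brute(data)

    def test_pi_matches_brute_force(self, rng):
        for _ in range(100):
            data = random_matrix(rng)
            pi = nt.nucleotide_diversity(make_matrix(data), 10_000) * 10_000
            assert pi == pytest.approx(pi_locus_brute(data))

    def test_tajima_d_matches_independent_recomputation(self, rng):
        for _ in range(100):
            data = random_matrix(rng)
            expected = tajima_d_brute(data)
            got = nt.tajimas_D(make_matrix(data))
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)

    @pytest.mark.parametrize("polarized", [True, False])
    def test_fu_li_matches_direct_formulas(self, rng, polarized):
        for _ in range(100):
            data = random_matrix(rng)
            eD, eF = fuli_brute(data, polarized=polarized)
            gD, gF = nt.fu_li_D_F(make_matrix(data), polarized=polarized)
            if eD is None:
                assert gD is None and gF is None
            else:
                assert gD == pytest.approx(eD)
                assert gF == pytest.approx(eF)


class TestTajimaEdgeCases:
    def test_undefined_when_no_segregating_sites(self):
        assert nt.tajimas_D(make_matrix(np.zeros((4, 6)))) is None

    def test_fu_li_undefined_when_no_segregating_sites(self):
        assert nt.fu_li_D_F(make_matrix(np.zeros((4, 6)))) == (None, None)

    def test_fu_li_sign_forced_by_singletons(self):
        # no derived singletons, S > 0 -> D > 0
        data = np.zeros((6, 10), dtype=int)
        data[:, :5] = 1
        D, _ = nt.fu_li_D_F(make_matrix(data))
        assert D > 0
        # every mutation a derived singleton -> D < 0
        data2 = np.eye(8, 10, dtype=int)
        D2, _ = nt.fu_li_D_F(make_matrix(data2))
        assert D2 < 0

    def test_polarized_requires_derived_coding(self):
        H = make_matrix(np.eye(3, 6, dtype=int), coding="ref/alt")
        with pytest.raises(ValueError, match="coding"):
            nt.fu_li_D_F(H, polarized=True)


class TestSimulationPvalues:
    def test_plus_one_rule_observed_beyond_all_replicates(self):
        null = np.linspace(-2, 2, 999)
        assert nt.pvalue_from_null(3.0, null, "upper") == pytest.approx(1 / 1000)

    def test_observed_at_median_gives_half(self):
        null = np.linspace(-2, 2, 999)
        assert nt.pvalue_from_null(0.0, null, "upper") == pytest.approx(0.5, abs=0.01)

    def test_neutrality_pvalue_requires_defined_observation(self):
        with pytest.raises(ValueError):
            nt.neutrality_pvalue(None, CoalescentConfig(n=10, fixed_S=5), "tajima_d")

    def test_null_calibration_under_matched_null(self):
        """p-values of neutral replicates against the same null are uniform:
        one-tailed rejection at 0.05 lands in [0.035, 0.065]."""
        n, S = 20, 20
        null = nt.simulate_null_table(n, S, reps=4000, seed=10)["tajima_d"]
        rng = np.random.default_rng(11)
        tc = nt._tajima_constants(n)
        rejections = 0
        draws = 2000
        for _ in range(draws):
            d = nt._tajima_from_counts(simulate_sfs_counts(n, S, rng), n, tc)
            tail = "upper" if d >= 0 else "lower"
            # two one-sided tests at 0.025 each ~ size-0.05 procedure
            if nt.pvalue_from_null(d, null, tail) <= 0.025:
                rejections += 1
        assert 0.035 <= rejections / draws <= 0.065

    def test_fixed_s_null_reproduces_known_negative_bias(self):
        """Conditioning on S skews the SFS toward singletons; the mean of
        Tajima's D under the fixed-S null is ~ -0.1 at n=20, S=20 (checked
        against an independent msprime-tree oracle in test_simulate)."""
        null = nt.simulate_null_table(20, 20, reps=4000, seed=3)
        assert -0.16 < null["tajima_d"].mean() < -0.04
        # Fu & Li variance constants: null variance close to 1
        assert 0.85 < null["fuli_d"].var() < 1.15
        assert 0.85 < null["fuli_f"].var() < 1.25


class TestAdaptiveBH:
    def test_single_pvalue_unchanged(self):
        assert nt.abh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_ones_stay_one(self):
        assert np.allclose(nt.abh_adjust([1.0] * 5), 1.0)

    def test_matches_stepwise_oracle_on_hand_list(self):
        pvals = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205]
        expected, m0 = abh_brute(pvals)
        got = nt.abh_adjust(pvals)
        assert np.allclose(got, expected)
        assert nt.estimate_m0(pvals) == m0

    def test_matches_stepwise_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 25))
            p = np.clip(rng.random(m) ** rng.uniform(0.5, 3), 1e-12, 1.0)
            expected, _ = abh_brute(p)
            assert np.allclose(nt.abh_adjust(p), expected)

    def test_reduces_to_plain_bh_when_m0_equals_m(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.9, 0.95, 0.99, 0.8, 0.85]  # no signal: m0 estimate = m
        assert nt.estimate_m0(p) == len(p)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(nt.abh_adjust(p), np.maximum(bh, p))

    def test_adjusted_values_monotone_and_bounded(self, rng):
        p = np.sort(rng.random(12))
        adj = nt.abh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p).all() and (adj <= 1).all()

    def test_empty_and_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            nt.abh_adjust([])
        with pytest.raises(ValueError):
            nt.abh_adjust([0.0, 0.5])


class TestBattery:
    def test_planted_balanced_locus_detected(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        eur = H.subset_chromosomes(np.flatnonzero(groups == "EUR"))
        res = nt.neutrality_battery(eur, "locus", 4000, group="EUR", reps=2000, seed=5)
        assert res.tajima_d > 1.5 and res.fuli_f > 0
        assert res.p_tajima_d <= 0.01
        assert res.tails["p_tajima_d"] == "upper"

    def test_table_adjusts_all_defined_pvalues(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        results = [
            nt.neutrality_battery(
                H.subset_chromosomes(np.flatnonzero(groups == g)),
                "locus", 4000, group=g, reps=400, seed=i,
            )
            for i, g in enumerate(("EUR", "EAS"))
        ]
        df = nt.neutrality_table(results)
        assert len(df) == 2
        for col in ("adj_p_pi", "adj_p_tajima_d"):
            assert (df[col] >= df[col.replace("adj_", "")] - 1e-12).all()

    def test_zero_segregating_sites_skips_pvalues(self):
        res = nt.neutrality_battery(make_matrix(np.zeros((3, 6))), "x", 100, reps=100)
        assert res.tajima_d is None and res.p_tajima_d is None
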