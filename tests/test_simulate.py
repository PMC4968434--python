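import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from balscan import neutrality as nt
from balscan.fst import fst_per_site
from balscan.simulate import (
    BackgroundConfig,
    CoalescentConfig,
    DeepCladeConfig,
    StructuredConfig,
    _branch_leaf_counts,
    make_cohort,
    simulate_background_fst,
    simulate_bn_genotypes,
    simulate_coalescent,
    simulate_deep_clades,
    simulate_island,
    simulate_sfs_counts,
)


class TestCoalescentConfig:
    def test_theta_and_fixed_s_mutually_exclusive(self):
        with pytest.raises(ValueError):
            CoalescentConfig(n=10, theta=5.0, fixed_S=5)
        with pytest.raises(ValueError):
            CoalescentConfig(n=10)

    def test_recombination_refused(self):
        with pytest.raises(NotImplementedError):
            CoalescentConfig(n=10, fixed_S=5, rho=1.0)


class TestKingmanCoalescent:
    def test_mean_pair_coalescence_time_is_one(self, rng):
        # E[T2] = 1 in units of 2N generations
        times = [_branch_leaf_counts(2, rng)[2] for _ in range(4000)]
        assert abs(np.mean(times) - 1.0) < 4 * np.std(times) / np.sqrt(len(times))

    def test_theta_mode_mean_segregating_sites(self):
        # E[S] = theta * sum_{i<n} 1/i = 5 * a_9 ~ 14.14
        theta, n, reps = 5.0, 10, 4000
        S = [
            simulate_coalescent(CoalescentConfig(n=n, theta=theta, seed=s))[0].n_sites
            for s in range(reps)
        ]
        expected = theta * nt.harmonic(n)
        assert abs(np.mean(S) - expected) < 4 * np.std(S) / np.sqrt(reps)

    def test_theta_mode_mean_pi_equals_theta(self):
        theta, n = 4.0, 12
        pis = []
        for s in range(2500):
            H, _ = simulate_coalescent(CoalescentConfig(n=n, theta=theta, seed=s))
            pis.append(nt.nucleotide_diversity(H, 10_000) * 10_000)
        assert abs(np.mean(pis) - theta) < 4 * np.std(pis) / np.sqrt(len(pis))

    def test_fixed_s_conditioning_is_exact(self):
        for s in range(30):
            H, _ = simulate_coalescent(CoalescentConfig(n=8, fixed_S=7, seed=s))
            assert H.n_sites == 7
            assert nt.segregating_sites(H) == 7

    def test_generator_is_pure_function_of_seed(self):
        cfg = CoalescentConfig(n=12, fixed_S=9, seed=42)
        H1, t1 = simulate_coalescent(cfg)
        H2, t2 = simulate_coalescent(cfg)
        assert np.array_equal(H1.data, H2.data)
        assert t1 == t2

    def test_matches_msprime_tree_oracle(self):
        """Mean fixed-S Tajima's D agrees with an independent coalescent
        implementation (msprime trees + proportional mutation placement)."""
        import msprime

        n, S, reps = 20, 20, 1500
        tc = nt._tajima_constants(n)
        mine = []
        rng = np.random.default_rng(0)
        for _ in range(reps):
            mine.append(nt._tajima_from_counts(simulate_sfs_counts(n, S, rng), n, tc))
        theirs = []
        rng2 = np.random.default_rng(1)
        for rep in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=0.5, random_seed=rep + 1
            )
            tree = ts.first()
            lens, cnts = [], []
            for u in tree.nodes():
                if tree.parent(u) != -1:
                    lens.append(tree.branch_length(u))
                    cnts.append(tree.num_samples(u))
            lens = np.array(lens)
            idx = rng2.choice(len(lens), size=S, p=lens / lens.sum())
            theirs.append(nt._tajima_from_counts(np.array(cnts)[idx], n, tc))
        se = np.sqrt(np.var(mine) / reps + np.var(theirs) / reps)
        assert abs(np.mean(mine) - np.mean(theirs)) < 4 * se


class TestIslandModel:
    def test_zero_migration_requires_forced_merge(self):
        with pytest.raises(ValueError, match="merge"):
            StructuredConfig(demes=2, n_per_deme=(10, 10), migration_4Nm=0.0)

    def test_panmixia_limit_gives_near_zero_fst(self):
        vals = []
        for s in range(25):
            H, lab = simulate_island(
                StructuredConfig(demes=2, n_per_deme=(20, 20), migration_4Nm=1000.0, seed=s),
                theta=5.0,
            )
            if H.n_sites == 0:
                continue
            # Hudson estimator: sample-size corrected, unbiased around 0
            f = fst_per_site(
                H, np.flatnonzero(lab == 0), np.flatnonzero(lab == 1), estimator="hudson"
            )
            vals += list(f[~np.isnan(f)])
        assert abs(np.mean(vals)) < 0.02

    def test_fst_decreases_with_migration(self):
        def mean_fst(M, seeds):
            vals = []
            for s in seeds:
                H, lab = simulate_island(
                    StructuredConfig(demes=2, n_per_deme=(20, 20), migration_4Nm=M, seed=s),
                    theta=3.0,
                )
                if H.n_sites:
                    f = fst_per_site(H, np.flatnonzero(lab == 0), np.flatnonzero(lab == 1))
                    vals += list(f[~np.isnan(f)])
            return np.mean(vals)

        assert mean_fst(1.0, range(40)) > mean_fst(10.0, range(40))

    def test_chromosome_bookkeeping(self):
        H, lab = simulate_island(
            StructuredConfig(demes=2, n_per_deme=(20, 14), migration_4Nm=2.0, seed=3), theta=4.0
        )
        assert H.n_chromosomes == 34
        assert (lab == 0).sum() == 20 and (lab == 1).sum() == 14


class TestDeepClades:
    def test_monomorphic_clades_give_positive_tajima_d(self):
        cfg = DeepCladeConfig(
            freq_cladeA_per_group={"G": 0.5},
            n_per_group={"G": 40},
            split_depth=10,
            within_clade=CoalescentConfig(n=2, fixed_S=0),
            seed=5,
        )
        H, clades, _ = simulate_deep_clades(cfg)
        assert nt.tajimas_D(H) > 1.0

    def test_clade_a_absent_leaves_only_b_variation(self):
        cfg = DeepCladeConfig(
            freq_cladeA_per_group={"G": 0.0},
            n_per_group={"G": 30},
            split_depth=10,
            within_clade=CoalescentConfig(n=2, fixed_S=6),
            seed=6,
        )
        H, clades, _ = simulate_deep_clades(cfg)
        assert set(clades) == {"B"}
        assert not [s for s in H.sites if s.id.startswith("split")]
        assert H.n_sites <= 6

    def test_pi_matches_brute_force_pairwise_differences(self, deep_clade_scenario):
        from oracles import pi_locus_brute

        _, H, clades, _ = deep_clade_scenario
        pi = nt.nucleotide_diversity(H, 4000) * 4000
        assert pi == pytest.approx(pi_locus_brute(H.data))
        # split sites dominate: inter-clade pairs differ by >= split_depth
        fA = (clades == "A").mean()
        assert pi >= 2 * fA * (1 - fA) * 20 * 0.9

    def test_truth_labels_recoverable_by_clustering(self, deep_clade_scenario):
        _, H, clades, _ = deep_clade_scenario
        Z = linkage(pdist(H.data.T, metric="hamming"), method="single")
        found = fcluster(Z, t=2, criterion="maxclust")
        agreement = max(((found == k) == (clades == "A")).mean() for k in (1, 2))
        assert agreement >= 0.99


class TestMakeCohort:
    def test_zero_enrichment_preserves_source_frequency(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        G, panel, truth, cohort = make_cohort(
            H, groups, clades, disease_group="D", disease_source="EUR",
            n_disease=500, disease_enrichment=0.0, seed=1,
        )
        src = (clades[groups == "EUR"] == "A").mean()
        dis = np.mean(
            [(a == "A") + (b == "A") for s, (a, b) in truth.items() if s.startswith("D_")]
        ) / 2
        assert abs(dis - src) < 0.05

    def test_enrichment_outside_unit_interval_raises(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        with pytest.raises(ValueError, match="outside"):
            make_cohort(
                H, groups, clades, disease_group="D", disease_source="EUR",
                n_disease=5, disease_enrichment=0.9, seed=1,
            )

    def test_fixed_seed_reproduces_cohort_exactly(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        kw = dict(disease_group="D", disease_source="EUR", n_disease=10,
                  disease_enrichment=0.03, seed=9)
        G1, *_ = make_cohort(H, groups, clades, **kw)
        G2, *_ = make_cohort(H, groups, clades, **kw)
        assert np.array_equal(G1.data, G2.data)

    def test_homozygote_fraction_matches_hardy_weinberg(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        _, _, truth, _ = make_cohort(
            H, groups, clades, disease_group="D", disease_source="EUR",
            n_disease=4000, disease_enrichment=0.03, seed=2,
        )
        pairs = [v for s, v in truth.items() if s.startswith("D_")]
        p = np.mean([(a == "A") + (b == "A") for a, b in pairs]) / 2
        hom = np.mean([a == b == "A" for a, b in pairs])
        assert hom == pytest.approx(p * p, abs=0.02)


class TestBackgroundFst:
    CFG = dict(n_per_cluster={"A": 100, "B": 100}, seed=3)

    def test_no_differentiation_limit(self):
        bg = simulate_background_fst(BackgroundConfig(n_snps=3000, fst_target=1e-4, **self.CFG))
        assert np.percentile(bg[("A", "B")], 99) < 0.05

    def test_hudson_mean_matches_balding_nichols_f(self):
        bg = simulate_background_fst(
            BackgroundConfig(n_snps=10000, fst_target=0.1, **self.CFG), estimator="hudson"
        )
        assert bg[("A", "B")].mean() == pytest.approx(0.1, rel=0.2)

    def test_wright_mean_matches_gst_expectation(self):
        # two-population G_ST expectation under Balding-Nichols: (F/2)/(1-F/2)
        F = 0.1
        bg = simulate_background_fst(
            BackgroundConfig(n_snps=10000, fst_target=F, **self.CFG), estimator="wright"
        )
        assert bg[("A", "B")].mean() == pytest.approx((F / 2) / (1 - F / 2), rel=0.2)

    def test_fixed_seed_reproduces_distribution(self):
        cfg = BackgroundConfig(n_snps=500, fst_target=0.05, **self.CFG)
        a = simulate_background_fst(cfg)[("A", "B")]
        b = simulate_background_fst(cfg)[("A", "B")]
        assert np.array_equal(a, b)


def test_bn_genotypes_shapes_and_labels():
    G, labels = simulate_bn_genotypes(50, 0.1, {"X": 10, "Y": 12}, seed=0)
    assert G.data.shape == (22, 50)
    assert list(labels[:10]) == ["X"] * 10
    assert set(np.unique(G.data)) <= {0, 1, 2}
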