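import itertools

import networkx as nx
import numpy as np
import pytest

from balscan import network as NET

from conftest import make_matrix


class TestCondense:
    def test_identical_chromosomes_collapse_to_one_node(self):
        H = make_matrix(np.zeros((4, 10)))
        counts = NET.condense(H)
        assert counts == {"0000": {"all": 10}}

    def test_two_clade_fixture_exact_tallies(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        counts = NET.condense(H)
        total = sum(sum(d.values()) for d in counts.values())
        assert total == H.n_chromosomes

    def test_per_group_counts_sum_to_group_sizes(self):
        data = np.array([[1, 1, 0, 0], [0, 1, 0, 0]])
        H = make_matrix(data)
        panel_map = {"s0": "X", "s1": "Y"}
        from balscan.core import PopulationPanel

        panel = PopulationPanel(dict(panel_map), dict(panel_map))
        counts = NET.condense(H, panel)
        per_group = {}
        for d in counts.values():
            for g, c in d.items():
                per_group[g] = per_group.get(g, 0) + c
        assert per_group == {"X": 2, "Y": 2}


class TestBuildNetwork:
    def test_two_haplotypes_single_edge_with_k_mutations(self):
        net = NET.build_mj_network(["00000", "11100"])
        assert net.graph.number_of_edges() == 1
        d = net.graph.edges["00000", "11100"]
        assert d["weight"] == 3
        assert sorted(d["sites"]) == [0, 1, 2]

    def test_three_cycle_resolved_by_median_vector(self):
        """{110, 101, 011}: the majority median 111 turns the 3-cycle of
        cost 4 into a star of cost 3 (the optimal Steiner solution)."""
        net = NET.build_mj_network(["110", "101", "011"])
        assert "111" in net.graph.nodes
        assert not net.graph.nodes["111"]["sampled"]
        weights = [d for _, _, d in net.graph.edges(data="weight")]
        assert sorted(weights) == [1, 1, 1]
        # verify optimality exhaustively over all 3-site Steiner points
        best = min(
            sum(sum(a != b for a, b in zip(m, h)) for h in ("110", "101", "011"))
            for m in ("".join(bits) for bits in itertools.product("01", repeat=3))
        )
        assert sum(weights) == best

    def test_homoplasy_free_data_yields_max_parsimony_tree(self, rng):
        """Each site mutates once on a random genealogy: the network must be
        a tree whose total length equals the number of sites."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            leaves = ["0" * 12]
            while len(leaves) < 7:
                parent = leaves[int(r.integers(len(leaves)))]
                site = len(leaves) + 4  # unique site per branch event
                child = parent[:site] + "1" + parent[site + 1 :]
                leaves.append(child)
            net = NET.build_mj_network(sorted(set(leaves)))
            G = net.graph
            assert nx.is_connected(G)
            total = sum(d for _, _, d in G.edges(data="weight"))
            n_sites = len({i for h in leaves for i in range(12) if h[i] == "1"})
            assert total == n_sites  # parsimony score of a perfect phylogeny
            assert G.number_of_edges() == G.number_of_nodes() - 1  # tree

    def test_non_binary_haplotypes_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            NET.build_mj_network(["0A1", "001"])
        with pytest.raises(ValueError, match="2 distinct"):
            NET.build_mj_network(["010"])


class TestRooting:
    def test_outgroup_equal_to_sampled_node(self):
        net = NET.build_mj_network(["000", "110"])
        NET.root_by_outgroup(net, "000")
        assert net.root == "000"

    def test_tie_broken_by_count_then_lexicographic(self):
        net = NET.build_mj_network({"100": {"all": 5}, "010": {"all": 2}, "111": {"all": 1}})
        NET.root_by_outgroup(net, "000")  # 100 and 010 both at distance 1
        assert net.root == "100"
        net2 = NET.build_mj_network({"100": {"all": 2}, "010": {"all": 2}})
        NET.root_by_outgroup(net2, "000")
        assert net2.root == "010"  # equal counts -> lexicographically smaller

    def test_planted_ancestral_haplotype_recovered(self, deep_clade_scenario):
        _, H, clades, _ = deep_clade_scenario
        counts = NET.condense(H)
        net = NET.build_mj_network(counts)
        NET.root_by_outgroup(net, "0" * H.n_sites)
        # the root must be a clade-B haplotype: no derived split alleles
        split_idx = [i for i, s in enumerate(H.sites) if s.id.startswith("split")]
        assert all(net.root[i] == "0" for i in split_idx)


class TestRhoTmrca:
    def test_star_with_unsampled_root_gives_rho_one(self):
        net = NET.build_mj_network(["110", "101", "011"])  # star around median 111
        net.root = "111"
        est = NET.rho_tmrca(net, NET.CalibrationInfo(120, 6e6))
        assert est.rho == pytest.approx(1.0)

    def test_all_chromosomes_at_root_give_zero(self):
        net = NET.build_mj_network({"00": {"all": 10}, "11": {"all": 0}})
        net.root = "00"
        est = NET.rho_tmrca(net, NET.CalibrationInfo(120, 6e6))
        assert est.rho == 0.0 and est.tmrca_years == 0.0

    def test_calibration_arithmetic(self):
        # 120 fixed differences over 6 My -> 1e-5 per locus per year;
        # rho = 15 -> TMRCA = 1.5 My
        calib = NET.CalibrationInfo(fixed_differences=120, divergence_time_years=6e6)
        assert calib.rate_per_year == pytest.approx(1e-5)
        net = NET.build_mj_network({"0" * 15: {"all": 0}, "1" * 15: {"all": 7}})
        net.root = "0" * 15
        est = NET.rho_tmrca(net, calib)
        assert est.rho == pytest.approx(15.0)
        assert est.tmrca_years == pytest.approx(1.5e6)

    def test_sigma_matches_hand_computation(self):
        net = NET.build_mj_network({"000": {"all": 2}, "110": {"all": 1}, "111": {"all": 1}})
        net.root = "000"
        est = NET.rho_tmrca(net, NET.CalibrationInfo(100, 1e6))
        # distances: 0 (x2), 2, 3; rho = 5/4; sigma = sqrt(4+9)/4
        assert est.rho == pytest.approx(5 / 4)
        assert est.sigma_rho == pytest.approx(np.sqrt(13) / 4)
        assert est.ci_years[0] <= est.tmrca_years <= est.ci_years[1]

    def test_unrooted_network_rejected(self):
        net = NET.build_mj_network(["00", "11"])
        with pytest.raises(ValueError, match="root"):
            NET.rho_tmrca(net, NET.CalibrationInfo(10, 1e6))


class TestDeepCladeRecovery:
    def test_clade_partition_and_rho_match_planted_truth(self, deep_clade_scenario):
        _, H, clades, groups = deep_clade_scenario
        counts = NET.condense(H)
        net = NET.build_mj_network(counts)
        # heaviest-edge cut separates the two planted clades
        sideA, sideB = NET.clade_partition(net)
        split_idx = [i for i, s in enumerate(H.sites) if s.id.startswith("split")]

        def clade_of(h):
            return "A" if h[split_idx[0]] == "1" else "B"

        sampled = [v for v in net.graph.nodes if net.graph.nodes[v].get("counts")]
        labels_a = {clade_of(h) for h in sideA if h in sampled}
        labels_b = {clade_of(h) for h in sideB if h in sampled}
        assert labels_a.isdisjoint(labels_b)

        # rho against the brute-force oracle: mean Hamming distance of every
        # chromosome to the planted ancestral (all-zero) haplotype
        NET.root_by_outgroup(net, "0" * H.n_sites)
        est = NET.rho_tmrca(net, NET.CalibrationInfo(120, 6e6))
        root_arr = np.array([int(c) for c in net.root], dtype=np.int8)
        oracle = np.abs(H.data - root_arr[:, None]).sum(axis=0).mean()
        assert est.rho == pytest.approx(oracle, rel=0.25)

    def test_network_conserves_sampled_chromosomes(self, deep_clade_scenario):
        _, H, _, _ = deep_clade_scenario
        net = NET.build_mj_network(NET.condense(H))
        assert net.total_sampled() == H.n_chromosomes
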