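"""Graph construction, singleton accounting, Leiden clustering, null
models, and cluster-size statistics."""

import numpy as np
import pytest
import scipy.sparse as sp

from pocketome import graph as gr
from pocketome.model import SimilarityMatrix
from pocketome.synthetic import planted_partition_matrix, sample_powerlaw_sizes


def sim_from_dense(dense, species="SP"):
    n = len(dense)
    ids = [f"pk{i}" for i in range(n)]
    return SimilarityMatrix(species, ids, sp.coo_matrix(np.asarray(dense, float)))


def random_sim(rng, n=30, p=0.15, high=20.0):
    dense = np.triu(rng.random((n, n)) < p, k=1) * rng.uniform(1.0, high, (n, n))
    return sim_from_dense(dense)


class TestBuildGraph:
    def test_single_pair_normalizes_to_one(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = 10.0
        g = gr.build_graph(sim_from_dense(dense))
        assert g.weighted_edges == [("pk0", "pk1", 1.0)]
        assert g.unweighted_edges == [("pk0", "pk1")]
        assert g.normalization_max == 10.0

    def test_boundary_score_excluded_strictly(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = 100.0
        dense[1, 2] = 10.0  # normalized exactly 0.1
        g = gr.build_graph(sim_from_dense(dense))
        assert ("pk1", "pk2") not in g.unweighted_edges
        assert ("pk0", "pk1") in g.unweighted_edges

    def test_empty_matrix_gives_no_edges(self):
        g = gr.build_graph(sim_from_dense(np.zeros((4, 4))))
        assert g.weighted_edges == [] and g.normalization_max is None

    def test_edge_set_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sim = random_sim(rng)
            g = gr.build_graph(sim)
            dense = sim.scores.toarray()
            mx = dense.max()
            brute = {
                (sim.pocket_ids[i], sim.pocket_ids[j])
                for i in range(sim.n_pockets)
                for j in range(i + 1, sim.n_pockets)
                if mx > 0 and dense[i, j] / mx > 0.1
            }
            assert set(g.unweighted_edges) == brute


class TestSingletons:
    def test_empty_matrix_all_singletons(self):
        sim = sim_from_dense(np.zeros((5, 5)))
        assert gr.find_singletons(sim) == frozenset(sim.pocket_ids)

    def test_fully_connected_none(self):
        dense = np.triu(np.ones((4, 4)), k=1)
        assert gr.find_singletons(sim_from_dense(dense)) == frozenset()


class TestComponents:
    def test_threshold_above_max_all_singletons(self):
        rng = np.random.default_rng(1)
        sim = random_sim(rng)
        res = gr.components_at_threshold(sim, raw_threshold=1e9)
        assert res.n_communities == 0 and res.n_singletons == sim.n_pockets

    def test_zero_threshold_connected_graph_one_component(self):
        dense = np.zeros((5, 5))
        for i in range(4):
            dense[i, i + 1] = 2.0
        res = gr.components_at_threshold(sim_from_dense(dense), raw_threshold=0.0)
        assert res.n_communities == 1 and res.largest_community == 5

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            sim = random_sim(rng, n=25)
            thr = float(rng.uniform(0, 15))
            res = gr.components_at_threshold(sim, thr)
            dense = sim.scores.toarray()
            parent = list(range(25))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(25):
                for j in range(i + 1, 25):
                    if dense[i, j] >= thr and dense[i, j] > 0:
                        parent[find(i)] = find(j)
            groups = {}
            for i in range(25):
                groups.setdefault(find(i), set()).add(sim.pocket_ids[i])
            want_comms = sorted(sorted(g) for g in groups.values() if len(g) > 1)
            want_singles = {next(iter(g)) for g in groups.values() if len(g) == 1}
            assert sorted(sorted(c) for c in res.communities) == want_comms
            assert res.singletons == frozenset(want_singles)

    def test_partition_and_unique_count_invariants(self):
        rng = np.random.default_rng(3)
        sim = random_sim(rng, n=40)
        res = gr.components_at_threshold(sim, 5.0)
        all_nodes = set().union(*res.communities, res.singletons)
        assert all_nodes == set(sim.pocket_ids)
        assert res.n_unique == res.n_communities + res.n_singletons


class TestLeiden:
    def test_two_disconnected_cliques(self):
        dense = np.zeros((8, 8))
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    if i < j:
                        dense[i, j] = 5.0
        res = gr.cluster_similarity(sim_from_dense(dense), seed=0)
        assert res.n_communities == 2
        assert {len(c) for c in res.communities} == {4}

    def test_complete_graph_single_community(self):
        dense = np.triu(np.full((10, 10), 4.0), k=1)
        res = gr.cluster_similarity(sim_from_dense(dense), seed=0)
        assert res.n_communities == 1 and res.largest_community == 10

    def test_separable_planted_communities_recovered(self):
        sim, truth = planted_partition_matrix("SP", [15, 10, 6, 4, 2], 5, seed=3)
        res = gr.cluster_similarity(sim, seed=1)
        assert sorted(map(sorted, res.communities)) == sorted(map(sorted, truth.communities))
        assert res.alignment_singletons == truth.singletons

    def test_seed_reproducible(self):
        sim, _ = planted_partition_matrix("SP", [20, 15, 10], 5, seed=4, density=0.2)
        a = gr.cluster_similarity(sim, seed=7)
        b = gr.cluster_similarity(sim, seed=7)
        assert a.communities == b.communities

    def test_no_intercommunity_edges_equals_components(self):
        sim, _ = planted_partition_matrix("SP", [9, 7, 5], 3, seed=5)
        leiden = gr.cluster_similarity(sim, seed=0)
        comps = gr.components_at_threshold(sim, raw_threshold=1e-12)
        assert sorted(map(sorted, leiden.communities)) == sorted(
            map(sorted, comps.communities)
        )


class TestRewire:
    def test_degree_multiset_preserved_node_by_node(self):
        sim, _ = planted_partition_matrix("SP", [10, 8, 4], 3, seed=6)
        g = gr.build_graph(sim)
        rewired = gr.rewire_degree_preserving(g, seed=1)
        assert g.degree_sequence() == rewired.degree_sequence()
        assert len(rewired.unweighted_edges) == len(g.unweighted_edges)

    def test_two_edge_path_unchanged(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = dense[1, 2] = 5.0
        g = gr.build_graph(sim_from_dense(dense))
        rewired = gr.rewire_degree_preserving(g, seed=0)
        assert set(rewired.unweighted_edges) == set(g.unweighted_edges)

    def test_randomization_changes_triangles(self):
        import networkx as nx

        sim, _ = planted_partition_matrix("SP", [12, 10, 8, 8, 6], 0, seed=7, density=0.6)
        g = gr.build_graph(sim)
        base = sum(nx.triangles(g.to_networkx()).values()) / 3
        counts = []
        for s in range(15):
            r = gr.rewire_degree_preserving(g, seed=s)
            counts.append(sum(nx.triangles(r.to_networkx()).values()) / 3)
        assert np.mean(counts) < base  # clique structure destroyed on average
        assert len(set(counts)) > 1


class TestOtherNulls:
    def test_random_graph_preserves_counts(self):
        sim, _ = planted_partition_matrix("SP", [10, 6], 4, seed=8)
        g = gr.build_graph(sim)
        null = gr.random_graph_same_density(g, seed=3)
        assert len(null.nodes) == len(g.nodes)
        assert len(null.unweighted_edges) == len(g.unweighted_edges)

    def test_two_seeds_differ_on_big_graphs(self):
        sim, _ = planted_partition_matrix("SP", [40, 30, 30], 0, seed=9, density=0.2)
        g = gr.build_graph(sim)
        a = gr.random_graph_same_density(g, seed=1)
        b = gr.random_graph_same_density(g, seed=2)
        assert set(a.unweighted_edges) != set(b.unweighted_edges)
        ra = gr.rewire_degree_preserving(g, seed=1)
        rb = gr.rewire_degree_preserving(g, seed=2)
        assert set(ra.unweighted_edges) != set(rb.unweighted_edges)

    def test_score_permutation_preserves_multiset_and_symmetry(self):
        rng = np.random.default_rng(4)
        sim = random_sim(rng, n=30)
        null = gr.randomize_score_matrix(sim, seed=5)
        assert sorted(sim.scores.data) == pytest.approx(sorted(null.scores.data))
        assert (null.scores != null.scores.T).nnz == 0


class TestClusterSizes:
    def test_histogram_of_equal_sizes(self):
        res = gr.ClusteringResult(
            "SP",
            [frozenset({f"a{i}", f"b{i}"}) for i in range(3)],
            frozenset(),
        )
        assert gr.cluster_size_histogram(res) == {2: 3}

    def test_conservation(self):
        sim, truth = planted_partition_matrix("SP", [8, 5, 5, 3], 6, seed=10)
        res = gr.cluster_similarity(sim, seed=0)
        hist = gr.cluster_size_histogram(res)
        assert sum(s * f for s, f in hist.items()) == res.n_pockets - res.n_singletons

    def test_power_law_slope_recovered(self):
        rng = np.random.default_rng(11)
        sizes = sample_powerlaw_sizes(rng, 1000, exponent=2.0, s_max=500)
        res = gr.ClusteringResult(
            "SP",
            [frozenset(f"c{k}_{i}" for i in range(s)) for k, s in enumerate(sizes)],
            frozenset(),
        )
        hist = gr.cluster_size_histogram(res)
        slope = gr.size_distribution_slope(hist)
        assert slope == pytest.approx(-2.0, abs=0.3)
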