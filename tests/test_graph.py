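"""Thresholding and graph metrics against brute-force oracles."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest
from oracles import brute_L_E, brute_clustering

from metabnet.graph import (
    DistanceMatrix,
    ThresholdedGraph,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    network_metrics,
    proportional_threshold,
    rewire_null,
    shortest_path_lengths,
    small_worldness,
    threshold_adjacency,
)
from metabnet.synthetic import random_graph, ring_lattice_graph


def binary_graph(edges, n):
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1.0
    m = n * (n - 1) // 2
    return ThresholdedGraph(adjacency=adj, density=max(len(edges), 1) / m, mode="binary")


class TestProportionalThreshold:
    def test_keeps_the_largest_weights(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 1, (4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = proportional_threshold(w, density=0.5, mode="weighted")
        assert g.n_edges == 3
        iu = np.triu_indices(4, k=1)
        kept = np.sort(g.adjacency[iu])[-3:]
        assert np.allclose(kept, np.sort(w[iu])[-3:])

    def test_full_density_keeps_all_edges(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = proportional_threshold(w, density=1.0)
        assert g.n_edges == 15

    def test_edge_count_follows_rounding(self):
        n = 10
        m = n * (n - 1) // 2  # 45
        rng = np.random.default_rng(2)
        w = rng.uniform(0.1, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        for density in (0.1, 0.25, 0.5, 0.9):
            g = proportional_threshold(w, density=density)
            assert g.n_edges == int(np.floor(density * m + 0.5))

    def test_too_low_density_rejected(self):
        w = np.eye(4)
        with pytest.raises(ValueError, match="density too low"):
            proportional_threshold(w, density=0.01)

    def test_tie_break_by_index_order(self):
        # all off-diagonal weights equal: ties everywhere at the cut
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 1.0)
        g = proportional_threshold(w, density=0.5, mode="binary")
        iu = np.triu_indices(4, k=1)
        kept = [(i, j) for i, j in zip(*iu) if g.adjacency[i, j]]
        # canonical order: first 3 pairs in lexicographic (i, j)
        assert kept == [(0, 1), (0, 2), (0, 3)]

    def test_negative_edges_excluded_from_weighted_mode(self):
        w = np.array(
            [
                [1.0, 0.9, -0.8, 0.1],
                [0.9, 1.0, 0.2, -0.9],
                [-0.8, 0.2, 1.0, 0.3],
                [0.1, -0.9, 0.3, 1.0],
            ]
        )
        g = proportional_threshold(w, density=1.0, mode="weighted", ranking="signed")
        assert np.all(g.adjacency >= 0)
        g_bin = proportional_threshold(w, density=1.0, mode="binary")
        assert g_bin.n_edges == 6


class TestAnalyticValues:
    def test_complete_graph_metrics_are_one(self):
        g = binary_graph(list(combinations(range(5), 2)), 5)
        c, _ = clustering_coefficient(g)
        d = shortest_path_lengths(g)
        assert c == pytest.approx(1.0)
        assert global_efficiency(d) == pytest.approx(1.0)
        assert characteristic_path_length(d)[0] == pytest.approx(1.0)

    def test_triangle_clusters_fully(self):
        g = binary_graph([(0, 1), (1, 2), (0, 2)], 3)
        assert clustering_coefficient(g)[0] == pytest.approx(1.0)

    def test_path_graph_p3(self):
        g = binary_graph([(0, 1), (1, 2)], 3)
        c, _ = clustering_coefficient(g)
        d = shortest_path_lengths(g)
        assert c == pytest.approx(0.0)
        assert d.d[0, 2] == pytest.approx(2.0)
        assert characteristic_path_length(d)[0] == pytest.approx(4.0 / 3.0)
        assert global_efficiency(d) == pytest.approx(5.0 / 6.0)

    def test_k4_minus_an_edge(self):
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]  # missing (2, 3)
        g = binary_graph(edges, 4)
        c, ci = clustering_coefficient(g)
        assert ci == pytest.approx([2 / 3, 2 / 3, 1.0, 1.0])
        assert c == pytest.approx(5.0 / 6.0)

    def test_disconnected_dyads_have_infinite_cross_distances(self):
        g = binary_graph([(0, 1), (2, 3)], 4)
        d = shortest_path_lengths(g)
        assert np.isinf(d.d[0, 2]) and np.isinf(d.d[1, 3])
        L, frac = characteristic_path_length(d)
        assert L == pytest.approx(1.0)
        assert frac == pytest.approx(8 / 12)

    def test_isolated_node_unreachable_fraction(self):
        n = 5
        g = binary_graph(list(combinations(range(4), 2)), n)
        _, frac = characteristic_path_length(shortest_path_lengths(g))
        assert frac == pytest.approx(2 * (n - 1) / (n * (n - 1)))

    def test_empty_graph_efficiency_zero(self):
        d = DistanceMatrix(d=np.where(np.eye(3, dtype=bool), 0.0, np.inf))
        assert global_efficiency(d) == 0.0
        with pytest.raises(ValueError):
            characteristic_path_length(d)


@pytest.fixture(scope="module")
def atlas_graphs():
    """All connected graphs with 3-6 nodes, from the graph atlas."""
    graphs = []
    for g in nx.graph_atlas_g()[1:]:
        n = g.number_of_nodes()
        if 3 <= n <= 6 and nx.is_connected(g) and g.number_of_edges() >= 1:
            graphs.append(nx.to_numpy_array(g))
    assert len(graphs) > 100
    return graphs


class TestOracleEquivalence:

    def test_clustering_matches_triangle_enumeration_exactly(self, atlas_graphs):
        for adj in atlas_graphs:
            n = adj.shape[0]
            g = ThresholdedGraph(adjacency=adj, density=0.5, mode="binary")
            mine, _ = clustering_coefficient(g)
            assert mine == pytest.approx(brute_clustering(adj), abs=1e-12)

    def test_paths_and_efficiency_match_exhaustive_search(self, atlas_graphs):
        for adj in atlas_graphs:
            g = ThresholdedGraph(adjacency=adj, density=0.5, mode="binary")
            metrics = network_metrics(adj, "binary")
            L, E = brute_L_E(adj)
            assert metrics.L == pytest.approx(L, abs=1e-12)
            assert metrics.E == pytest.approx(E, abs=1e-12)

    def test_weighted_six_node_paths_match_brute_force(self):
        # weighted oracle: exhaustive enumeration over all simple paths
        rng = np.random.default_rng(12)
        w = rng.uniform(0.2, 1.0, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        w[w < 0.45] = 0.0  # sparsify
        g = ThresholdedGraph(adjacency=w, density=0.5, mode="weighted")
        d = shortest_path_lengths(g).d
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
        for s in range(6):
            for t in range(6):
                if s == t:
                    continue
                best = np.inf
                for r in range(0, 5):
                    for mid in permutations([k for k in range(6) if k not in (s, t)], r):
                        nodes = (s, *mid, t)
                        cost = sum(lengths[u, v] for u, v in zip(nodes, nodes[1:]))
                        best = min(best, cost)
                assert d[s, t] == pytest.approx(best, abs=1e-9)


class TestModeConsistency:
    def test_weighted_reduces_to_binary_with_equal_weights(self):
        rng = np.random.default_rng(4)
        mask = rng.random((8, 8)) < 0.4
        mask = np.triu(mask, 1)
        adj = (mask + mask.T).astype(float) * 0.7
        gw = ThresholdedGraph(adjacency=adj, density=0.4, mode="weighted")
        gb = ThresholdedGraph(adjacency=(adj > 0).astype(float), density=0.4, mode="binary")
        mw = network_metrics(gw.adjacency, "weighted")
        mb = network_metrics(gb.adjacency, "binary")
        assert mw.C == pytest.approx(mb.C, abs=1e-10)
        # weighted path lengths are 1/0.7 per hop
        assert mw.L == pytest.approx(mb.L / 0.7, abs=1e-10)

    def test_efficiency_nondecreasing_in_density(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0.05, 1, (20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        effs = []
        for density in (0.1, 0.3, 0.5, 0.7, 0.9):
            adj = threshold_adjacency(w, density, mode="weighted")
            effs.append(network_metrics(adj, "weighted").E)
        assert np.all(np.diff(effs) >= -1e-12)


@pytest.fixture(scope="module")
def weighted_graph():
    rng = np.random.default_rng(13)
    w = rng.uniform(0.1, 1, (20, 20))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return proportional_threshold(w, density=0.3, mode="weighted")


class TestRewiring:

    def test_nulls_preserve_edge_count_and_degrees(self, weighted_graph):
        nulls = rewire_null(weighted_graph, n_randomizations=5, seed=3)
        deg0 = (weighted_graph.adjacency > 0).sum(axis=1)
        for null in nulls:
            assert null.n_edges == weighted_graph.n_edges
            assert np.array_equal((null.adjacency > 0).sum(axis=1), deg0)

    def test_nulls_preserve_weight_multiset(self, weighted_graph):
        nulls = rewire_null(weighted_graph, n_randomizations=3, seed=4)
        w0 = np.sort(weighted_graph.weights())
        for null in nulls:
            assert np.allclose(np.sort(null.weights()), w0)

    def test_nulls_differ_from_input_and_are_seeded(self, weighted_graph):
        n1 = rewire_null(weighted_graph, n_randomizations=2, seed=5)
        n2 = rewire_null(weighted_graph, n_randomizations=2, seed=5)
        n3 = rewire_null(weighted_graph, n_randomizations=2, seed=6)
        assert np.allclose(n1[0].adjacency, n2[0].adjacency)
        assert not np.allclose(n1[0].adjacency, n3[0].adjacency)
        assert not np.allclose(n1[0].adjacency, weighted_graph.adjacency)

    def test_dense_graph_rewires_through_complement(self):
        rng = np.random.default_rng(14)
        w = rng.uniform(0.1, 1, (12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = proportional_threshold(w, density=0.85, mode="binary")
        nulls = rewire_null(g, n_randomizations=3, seed=7)
        deg0 = (g.adjacency > 0).sum(axis=1)
        moved = 0
        for null in nulls:
            assert np.array_equal((null.adjacency > 0).sum(axis=1), deg0)
            moved += int(not np.allclose(null.adjacency, g.adjacency))
        assert moved == 3

    def test_star_graph_falls_back_to_density_only(self):
        g = binary_graph([(0, j) for j in range(1, 8)], 8)
        nulls = rewire_null(g, n_randomizations=4, seed=8)
        for null in nulls:
            assert null.n_edges == 7

    def test_single_edge_rejected(self):
        g = binary_graph([(0, 1)], 4)
        with pytest.raises(ValueError, match="at least 2 edges"):
            rewire_null(g, n_randomizations=2, seed=0)


class TestSmallWorldness:
    def test_complete_graph_sigma_exactly_one(self):
        g = binary_graph(list(combinations(range(10), 2)), 10)
        sw = small_worldness(g, n_randomizations=10, seed=0)
        assert sw.gamma == 1.0 and sw.lam == 1.0 and sw.sigma == 1.0

    def test_ring_lattice_is_small_world(self):
        g = ring_lattice_graph(50, 6, rewire_p=0.08, seed=2)
        sw = small_worldness(g, n_randomizations=30, seed=1)
        assert sw.sigma > 1.0
        assert sw.gamma > 1.0

    def test_random_graph_sigma_near_one(self):
        g = random_graph(50, 0.3, seed=3)
        sw = small_worldness(g, n_randomizations=30, seed=2)
        assert 0.8 <= sw.sigma <= 1.2

    def test_sigma_invariant_to_node_relabeling(self):
        g = ring_lattice_graph(30, 4, rewire_p=0.1, seed=4)
        perm = np.random.default_rng(5).permutation(30)
        relabeled = ThresholdedGraph(
            adjacency=g.adjacency[np.ix_(perm, perm)], density=g.density, mode="binary"
        )
        sw1 = small_worldness(g, n_randomizations=60, seed=9)
        sw2 = small_worldness(relabeled, n_randomizations=60, seed=9)
        # same degree sequence and metric values; null means agree statistically
        assert sw1.c_real == pytest.approx(sw2.c_real, abs=1e-12)
        assert sw1.l_real == pytest.approx(sw2.l_real, abs=1e-12)
        assert sw1.sigma == pytest.approx(sw2.sigma, rel=0.1)

    def test_sigma_is_gamma_over_lambda(self):
        g = random_graph(30, 0.25, seed=6)
        sw = small_worldness(g, n_randomizations=20, seed=3)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam, abs=1e-12)
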