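import numpy as np
import pytest

from icovnet.metrics import (
    characteristic_path_length,
    clustering_coefficients,
    edge_betweenness,
    modularity_q,
    node_betweenness,
    normalized_small_world,
    rewire_degree_preserving,
    shortest_path_lengths,
    to_connection_length,
)
from icovnet.network import WeightedNetwork

from _oracles import (
    brute_force_betweenness,
    exhaustive_max_modularity,
    floyd_warshall,
    random_weighted_graph,
    weighted_modularity,
)


def net_from(weights, k=1.0):
    w = np.asarray(weights, dtype=float)
    return WeightedNetwork(w, [f"v{i}" for i in range(w.shape[0])], k)


def triangle(wab=1.0, wac=1.0, wbc=1.0):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = wab
    w[0, 2] = w[2, 0] = wac
    w[1, 2] = w[2, 1] = wbc
    return net_from(w)


def path_graph(n, weight=1.0):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = weight
    return net_from(w)


def star(n_leaves):
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = w[1:, 0] = 1.0
    return net_from(w)


def complete(n):
    w = np.ones((n, n)) - np.eye(n)
    return net_from(w)


def two_cliques(size=4):
    n = 2 * size
    w = np.zeros((n, n))
    for block in (range(size), range(size, n)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return net_from(w)


class TestClustering:
    def test_unit_triangle_is_fully_clustered(self):
        assert np.allclose(clustering_coefficients(triangle()), 1.0)

    def test_path_has_no_triangles(self):
        assert np.allclose(clustering_coefficients(path_graph(3)), 0.0)

    def test_weighted_triangle_geometric_mean(self):
        # (1 * 1 * 0.125)^(1/3) = 0.5 at the apex with degree 2
        c = clustering_coefficients(triangle(wbc=0.125))
        assert c[0] == pytest.approx(0.5, abs=1e-12)

    def test_weights_above_one_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.5
        net = WeightedNetwork.__new__(WeightedNetwork)
        net.weights, net.node_names, net.sparsity_k = w, ["a", "b", "c"], 1.0
        with pytest.raises(ValueError):
            clustering_coefficients(net)


class TestConnectionLength:
    def test_inverts_present_edges_only(self):
        net = triangle(wab=1.0, wac=0.5, wbc=0.25)
        lengths = to_connection_length(net)
        assert lengths[0, 1] == 1.0
        assert lengths[0, 2] == 2.0
        assert lengths[1, 2] == 4.0
        assert np.all(np.diag(lengths) == 0)

    def test_absent_edge_is_infinite(self):
        lengths = to_connection_length(path_graph(3))
        assert np.isinf(lengths[0, 2])


class TestShortestPaths:
    def test_chain_distance_accumulates(self):
        d = shortest_path_lengths(to_connection_length(path_graph(3)))
        assert d[0, 2] == pytest.approx(2.0)

    def test_relaxation_beats_direct_edge(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[0, 2] = w[2, 0] = 1 / 3  # direct length 3 vs two hops of 1
        d = shortest_path_lengths(to_connection_length(net_from(w)))
        assert d[0, 2] == pytest.approx(2.0)

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            w = random_weighted_graph(10, rng)
            lengths = to_connection_length(net_from(w))
            assert np.allclose(
                shortest_path_lengths(lengths), floyd_warshall(lengths), atol=1e-9
            )


class TestCharacteristicPathLength:
    def test_unit_chain_mean(self):
        d = shortest_path_lengths(to_connection_length(path_graph(3)))
        assert characteristic_path_length(d) == pytest.approx(4 / 3)

    def test_infinite_pairs_excluded(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0  # two disjoint unit edges
        d = shortest_path_lengths(to_connection_length(net_from(w)))
        assert characteristic_path_length(d) == pytest.approx(1.0)

    def test_complete_unit_graph_is_one(self):
        d = shortest_path_lengths(to_connection_length(complete(5)))
        assert characteristic_path_length(d) == pytest.approx(1.0)

    def test_edgeless_graph_raises(self):
        d = shortest_path_lengths(to_connection_length(net_from(np.zeros((3, 3)))))
        with pytest.raises(ValueError):
            characteristic_path_length(d)


class TestRewiring:
    def test_degree_sequence_and_weights_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            w = random_weighted_graph(10, rng, p=0.35)
            net = net_from(w)
            null = rewire_degree_preserving(net, swaps_per_edge=5, rng=rng)
            assert np.array_equal(
                np.sort(null.degrees()), np.sort(net.degrees())
            )
            triu = np.triu_indices(10, 1)
            assert np.allclose(
                np.sort(null.weights[triu]), np.sort(net.weights[triu])
            )

    def test_triangle_is_a_fixed_point(self):
        # no valid double-edge swap exists on a triangle
        null = rewire_degree_preserving(triangle(), rng=np.random.default_rng(1))
        assert np.array_equal(null.weights, triangle().weights)

    def test_rewiring_actually_moves_edges(self):
        rng = np.random.default_rng(3)
        w = random_weighted_graph(12, rng, p=0.3)
        net = net_from(w)
        null = rewire_degree_preserving(net, swaps_per_edge=10, rng=rng)
        assert not np.array_equal(null.weights, net.weights)


class TestSmallWorld:
    def test_complete_graph_normalizes_to_unity(self):
        gamma, lam, sigma = normalized_small_world(
            complete(8), n_null=5, rng=np.random.default_rng(0)
        )
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_sigma_is_gamma_over_lambda(self, cohort):
        from icovnet.network import build_participant_network, threshold_proportional
        from icovnet.network import zscore_cohort

        z = zscore_cohort(cohort)
        net = threshold_proportional(build_participant_network(z.values[0]), 0.2)
        gamma, lam, sigma = normalized_small_world(
            net, n_null=20, rng=np.random.default_rng(0)
        )
        assert sigma == pytest.approx(gamma / lam, rel=1e-12)

    def test_ring_lattice_is_small_world(self):
        # 18 nodes, 2 neighbors each side: classic high-clustering regime
        n = 18
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        gamma, lam, sigma = normalized_small_world(
            net_from(w), n_null=200, rng=np.random.default_rng(7)
        )
        assert sigma > 1


class TestModularity:
    def test_two_cliques_recover_half(self):
        q, partition = modularity_q(two_cliques(), n_runs=20, rng=np.random.default_rng(0))
        assert q == pytest.approx(0.5, abs=1e-9)
        assert sorted(sorted(b) for b in partition) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_two_cliques_match_exhaustive_optimum(self):
        best_q, best_p = exhaustive_max_modularity(two_cliques().weights)
        assert best_q == pytest.approx(0.5, abs=1e-12)
        q, _ = modularity_q(two_cliques(), n_runs=20, rng=np.random.default_rng(0))
        assert q <= best_q + 1e-9

    def test_complete_graph_has_no_structure(self):
        q, partition = modularity_q(complete(6), n_runs=20, rng=np.random.default_rng(0))
        assert q <= 1e-9
        assert weighted_modularity(complete(6).weights, [list(range(6))]) == pytest.approx(0.0)

    def test_heuristic_never_beats_exhaustive_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            w = random_weighted_graph(7, rng, p=0.45)
            q, _ = modularity_q(net_from(w), n_runs=20, rng=rng)
            best_q, _ = exhaustive_max_modularity(w)
            assert q <= best_q + 1e-9

    def test_edgeless_network_raises(self):
        with pytest.raises(ValueError):
            modularity_q(net_from(np.zeros((4, 4))), n_runs=5)


class TestBetweenness:
    def test_star_center_scores_pairs_among_leaves(self):
        lengths = to_connection_length(star(4))
        bw = node_betweenness(lengths)
        assert bw[0] == pytest.approx(6.0)  # (n-1)(n-2)/2 with n=5
        assert np.allclose(bw[1:], 0.0)

    def test_unit_chain_interior_nodes(self):
        bw = node_betweenness(to_connection_length(path_graph(4)))
        assert np.allclose(bw, [0, 2, 2, 0])

    def test_bridge_between_triangles_carries_all_crossings(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
            w[a, b] = w[b, a] = 1.0
        ebw = edge_betweenness(to_connection_length(net_from(w)))
        assert ebw[2, 3] == pytest.approx(9.0)  # 3x3 crossing pairs

    def test_complete_graph_edges_serve_only_their_endpoints(self):
        ebw = edge_betweenness(to_connection_length(complete(6)))
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(ebw[off], 1.0)

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            w = random_weighted_graph(n, rng, p=0.5)
            lengths = to_connection_length(net_from(w))
            node_oracle, edge_oracle = brute_force_betweenness(lengths)
            assert np.allclose(node_betweenness(lengths), node_oracle, atol=1e-9)
            assert np.allclose(edge_betweenness(lengths), edge_oracle, atol=1e-9)
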