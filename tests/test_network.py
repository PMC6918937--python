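"""Graph construction, C/L metrics, degree-preserving nulls, small-world index."""

import itertools

import networkx as nx
import numpy as np
import pytest

from fatiguenet import (
    BinaryGraph,
    WeightedAdjacency,
    binarize_by_degree,
    binarize_by_threshold,
    characteristic_path_length,
    clustering_coefficient,
    default_thresholds,
    generate_ws_graph,
    maslov_sneppen_rewire,
    small_world,
    threshold_sweep,
)
from fatiguenet.network import is_connected, write_graphml, write_pajek

from conftest import random_adjacency


def brute_force_clustering(g: BinaryGraph) -> float:
    """Triple enumeration oracle for the mean clustering coefficient."""
    a = g.adjacency
    n = g.n_nodes
    cis = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            cis.append(0.0)
            continue
        links = sum(
            1 for u, v in itertools.combinations(nbrs, 2) if a[u, v]
        )
        cis.append(2.0 * links / (k * (k - 1)))
    return sum(cis) / n


def brute_force_path_length(g: BinaryGraph) -> float:
    """Floyd-Warshall oracle for the mean shortest path over reachable pairs."""
    n = g.n_nodes
    inf = float("inf")
    d = [[0 if i == j else (1 if g.adjacency[i, j] else inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    vals = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < inf]
    return sum(vals) / len(vals)


def _graph_from_nx(g) -> BinaryGraph:
    nodes = sorted(g.nodes())
    adj = nx.to_numpy_array(g, nodelist=nodes) > 0
    return BinaryGraph(adj, tuple(str(v) for v in nodes))


def _random_graph(rng, n, p):
    a = rng.uniform(size=(n, n)) < p
    a = np.triu(a, k=1)
    a = a | a.T
    return BinaryGraph(a, tuple(f"v{i}" for i in range(n)))


class TestBinarizeByThreshold:
    def test_zero_threshold_gives_complete_graph(self, rng):
        adj = random_adjacency(rng, 19)
        g = binarize_by_threshold(adj, 0.0)
        assert g.n_edges == 171
        assert not g.isolated_nodes

    def test_threshold_above_max_empties_graph(self, rng):
        adj = random_adjacency(rng, 19)
        g = binarize_by_threshold(adj, adj.values.max() + 1)
        assert g.n_edges == 0
        assert len(g.isolated_nodes) == 19

    def test_four_node_worked_example(self):
        w = np.zeros((4, 4))
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        iu = np.triu_indices(4, k=1)
        w[iu] = vals
        w = w + w.T
        adj = WeightedAdjacency(w, ("a", "b", "c", "d"))
        assert binarize_by_threshold(adj, 0.35).n_edges == 3

    def test_ties_survive_at_threshold(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.25
        w[0, 2] = w[2, 0] = 0.10
        adj = WeightedAdjacency(w, ("a", "b", "c"))
        g = binarize_by_threshold(adj, 0.25)
        assert g.n_edges == 1 and g.adjacency[0, 1]


class TestBinarizeByDegree:
    @pytest.mark.parametrize("k,expected_edges", [(6, 57), (5, 48)])
    def test_edge_counts_at_19_nodes(self, rng, k, expected_edges):
        # round(19 * 5 / 2) = round(47.5) resolves half-up to 48
        g = binarize_by_degree(random_adjacency(rng, 19), k)
        assert g.n_edges == expected_edges

    def test_equal_weights_break_ties_lexicographically(self):
        w = np.full((5, 5), 0.4)
        np.fill_diagonal(w, 0.0)
        adj = WeightedAdjacency(w, tuple("abcde"))
        g = binarize_by_degree(adj, 2)  # m = 5 edges
        expected = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2)]
        assert g.edges == expected

    def test_keeps_largest_weights(self, rng):
        adj = random_adjacency(rng, 10)
        g = binarize_by_degree(adj, 3)  # m = 15
        kept = sorted(adj.values[i, j] for i, j in g.edges)
        iu = np.triu_indices(10, k=1)
        top = sorted(np.sort(adj.values[iu])[-15:])
        assert np.allclose(kept, top)

    def test_infeasible_degree_rejected(self, rng):
        with pytest.raises(ValueError):
            binarize_by_degree(random_adjacency(rng, 5), 5)
        with pytest.raises(ValueError):
            binarize_by_degree(random_adjacency(rng, 5), 0.5)


class TestMetricsClosedForms:
    def test_triangle_clustering(self):
        g = _graph_from_nx(nx.complete_graph(3))
        assert clustering_coefficient(g) == 1.0

    def test_star_clustering_zero(self):
        g = _graph_from_nx(nx.star_graph(4))
        assert clustering_coefficient(g) == 0.0

    def test_complete_graph_path_length_one(self):
        g = _graph_from_nx(nx.complete_graph(5))
        assert characteristic_path_length(g) == 1.0

    def test_path_graph_p4(self):
        g = _graph_from_nx(nx.path_graph(4))
        assert characteristic_path_length(g) == pytest.approx(5.0 / 3.0, abs=1e-14)

    def test_ring_lattice_k4_clustering(self):
        g = generate_ws_graph(19, 4, 0.0, seed=0)
        assert clustering_coefficient(g) == pytest.approx(0.5, abs=1e-14)

    def test_edgeless_graph_rejected(self):
        g = BinaryGraph(np.zeros((4, 4), dtype=bool), tuple("abcd"))
        with pytest.raises(ValueError):
            characteristic_path_length(g)

    def test_disconnected_uses_reachable_pairs(self):
        # two triangles: all reachable distances are 1
        g = _graph_from_nx(nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3)))
        assert not is_connected(g)
        assert characteristic_path_length(g) == 1.0


class TestMetricOracles:
    def test_all_small_connected_graphs(self):
        # exhaustive: every connected graph on 2..6 nodes from the atlas
        count = 0
        for g in nx.graph_atlas_g():
            if not (2 <= g.number_of_nodes() <= 6) or g.number_of_edges() == 0:
                continue
            if not nx.is_connected(g):
                continue
            bg = _graph_from_nx(g)
            assert clustering_coefficient(bg) == pytest.approx(
                brute_force_clustering(bg), abs=1e-12
            )
            assert characteristic_path_length(bg) == pytest.approx(
                brute_force_path_length(bg), abs=1e-12
            )
            count += 1
        assert count > 100

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_against_oracles_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        g = _random_graph(rng, int(rng.integers(4, 9)), rng.uniform(0.3, 0.8))
        if g.n_edges == 0:
            return
        c = clustering_coefficient(g)
        assert c == pytest.approx(brute_force_clustering(g), abs=1e-12)
        assert c == pytest.approx(
            nx.average_clustering(g.to_networkx(), count_zeros=True), abs=1e-12
        )
        length = characteristic_path_length(g)
        assert length == pytest.approx(brute_force_path_length(g), abs=1e-12)
        if is_connected(g):
            assert length == pytest.approx(
                nx.average_shortest_path_length(g.to_networkx()), abs=1e-12
            )


class TestMaslovSneppen:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_and_edge_count_preserved(self, seed):
        rng = np.random.default_rng(seed)
        g = _random_graph(rng, 19, 0.3)
        null = maslov_sneppen_rewire(g, seed=seed)
        assert np.array_equal(null.degrees, g.degrees)
        assert null.n_edges == g.n_edges

    def test_deterministic_given_seed(self, rng):
        g = _random_graph(rng, 15, 0.4)
        a = maslov_sneppen_rewire(g, seed=42)
        b = maslov_sneppen_rewire(g, seed=42)
        c = maslov_sneppen_rewire(g, seed=43)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert not np.array_equal(a.adjacency, c.adjacency)

    def test_actually_randomizes(self, rng):
        g = generate_ws_graph(19, 4, 0.0, seed=0)
        null = maslov_sneppen_rewire(g, seed=1)
        assert not np.array_equal(null.adjacency, g.adjacency)

    def test_triangle_admits_no_move(self):
        g = _graph_from_nx(nx.complete_graph(3))
        null = maslov_sneppen_rewire(g, seed=0)
        assert np.array_equal(null.adjacency, g.adjacency)

    def test_complete_graph_unchanged(self):
        g = _graph_from_nx(nx.complete_graph(7))
        null = maslov_sneppen_rewire(g, seed=0)
        assert np.array_equal(null.adjacency, g.adjacency)

    def test_dense_graph_rewires_through_complement(self):
        # near-complete graphs must still mix rather than stall
        g = _graph_from_nx(nx.complete_graph(10))
        a = g.adjacency.copy()
        a[0, 1] = a[1, 0] = False
        a[2, 5] = a[5, 2] = False
        a[3, 7] = a[7, 3] = False
        dense = BinaryGraph(a, g.labels)
        null = maslov_sneppen_rewire(dense, seed=3)
        assert np.array_equal(null.degrees, dense.degrees)
        assert not np.array_equal(null.adjacency, dense.adjacency)

    def test_star_graph_warns_and_preserves(self):
        g = _graph_from_nx(nx.star_graph(5))
        with pytest.warns(UserWarning):
            null = maslov_sneppen_rewire(g, seed=0, max_attempt_factor=2)
        assert np.array_equal(null.adjacency, g.adjacency)


class TestSmallWorld:
    def test_complete_graph_sigma_exactly_one(self):
        g = _graph_from_nx(nx.complete_graph(19))
        res = small_world(g, n_nulls=10, seed=0)
        assert res.sigma == 1.0
        assert res.C == res.C_rand == 1.0
        assert res.L == res.L_rand == 1.0

    def test_watts_strogatz_is_small_world(self):
        g = generate_ws_graph(19, 4, 0.1, seed=1)
        res = small_world(g, n_nulls=50, seed=0)
        assert res.sigma is not None and res.sigma > 1.0

    def test_triangle_free_nulls_leave_sigma_undefined(self):
        g = _graph_from_nx(nx.path_graph(4))
        res = small_world(g, n_nulls=5, seed=0)
        assert res.C_rand == 0.0
        assert res.sigma is None

    def test_reproducible(self, rng):
        g = _random_graph(rng, 19, 0.3)
        a = small_world(g, n_nulls=20, seed=5)
        b = small_world(g, n_nulls=20, seed=5)
        assert a == b


class TestThresholdSweep:
    def test_edge_count_monotone_nonincreasing(self, rng):
        adj = random_adjacency(rng, 19)
        sweep = threshold_sweep(adj, default_thresholds(), n_nulls=2, seed=0)
        counts = sweep.edge_counts
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_first_flagged_threshold_matches_weakest_node(self, rng):
        adj = random_adjacency(rng, 10)
        node_max = np.array(
            [np.delete(adj.values[i], i).max() for i in range(10)]
        )
        weakest = node_max.min()
        thresholds = tuple(np.round(np.linspace(0.01, 0.99, 30), 6))
        sweep = threshold_sweep(adj, thresholds, n_nulls=2, seed=0)
        flagged = [t for t, iso in zip(sweep.thresholds, sweep.isolated) if iso]
        expected_first = next(t for t in thresholds if t > weakest)
        assert flagged and min(flagged) == expected_first

    def test_uniform_weights_single_transition(self):
        w = np.full((19, 19), 0.5)
        np.fill_diagonal(w, 0.0)
        adj = WeightedAdjacency(w, tuple(f"v{i}" for i in range(19)))
        sweep = threshold_sweep(adj, (0.4, 0.5, 0.6), n_nulls=2, seed=0)
        assert sweep.edge_counts == (171, 171, 0)
        assert sweep.isolated == (False, False, True)

    def test_thresholds_must_ascend(self, rng):
        with pytest.raises(ValueError):
            threshold_sweep(random_adjacency(rng, 5), (0.3, 0.2), n_nulls=2, seed=0)

    def test_default_threshold_grid(self):
        thr = default_thresholds()
        assert len(thr) == 21
        assert thr[0] == 0.15 and thr[-1] == 0.35
        assert np.allclose(np.diff(thr), 0.01)


class TestNestedMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edges_never_lengthens_paths(self, seed):
        rng = np.random.default_rng(seed)
        g = _random_graph(rng, 12, 0.3)
        if not is_connected(g) or g.n_edges == 0:
            return
        a = g.adjacency.copy()
        empty = np.argwhere(~a & ~np.eye(12, dtype=bool))
        i, j = empty[rng.integers(len(empty))]
        a[i, j] = a[j, i] = True
        bigger = BinaryGraph(a, g.labels)
        assert characteristic_path_length(bigger) <= characteristic_path_length(g)


def test_graph_exports_roundtrip(tmp_path, rng):
    g = _random_graph(rng, 8, 0.4)
    write_pajek(g, tmp_path / "g.net")
    write_graphml(g, tmp_path / "g.graphml")
    back = nx.read_pajek(tmp_path / "g.net")
    assert back.number_of_nodes() == 8
    assert nx.Graph(back).number_of_edges() == g.n_edges
    back2 = nx.read_graphml(tmp_path / "g.graphml")
    assert back2.number_of_edges() == g.n_edges
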