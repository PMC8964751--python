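"""Pathway extraction: cost transforms, (k-)shortest paths vs brute-force
enumeration, residue frequencies, betweenness centralities."""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from nridyn.graph import InteractionMatrix
from nridyn.pathways import (
    PathGraph,
    build_path_graph,
    node_centrality,
    path_residue_frequency,
    shortest_paths,
)


def matrix_from_edges(n, edges):
    w = np.zeros((n, n))
    for i, j, weight in edges:
        w[i, j] = weight
    return InteractionMatrix(w)


def enumerate_simple_paths(g: nx.DiGraph, s, t):
    """Brute force: all simple paths with their costs, cheapest first."""
    paths = []
    for path in nx.all_simple_paths(g, s, t):
        cost = sum(g[u][v]["cost"] for u, v in zip(path, path[1:]))
        paths.append((cost, tuple(path)))
    return sorted(paths)


class TestBuildPathGraph:
    def test_full_weight_has_zero_cost_under_neg_log(self):
        m = matrix_from_edges(2, [(0, 1, 1.0)])
        g = build_path_graph(m, 0.5, "neg_log")
        assert g.graph[0][1]["cost"] == 0.0

    def test_half_weight_costs_ln_two(self):
        m = matrix_from_edges(2, [(0, 1, 0.5)])
        g = build_path_graph(m, 0.4, "neg_log")
        assert g.graph[0][1]["cost"] == pytest.approx(np.log(2), rel=1e-6)

    def test_reciprocal_transform(self):
        m = matrix_from_edges(2, [(0, 1, 0.5)])
        g = build_path_graph(m, 0.4, "reciprocal")
        assert g.graph[0][1]["cost"] == pytest.approx(2.0)

    @pytest.mark.parametrize("transform", ["neg_log", "reciprocal"])
    def test_stronger_edges_cost_less(self, transform):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.3, 1.0, size=(6, 6))
        np.fill_diagonal(w, 0.0)
        g = build_path_graph(InteractionMatrix(w), 0.3, transform)
        edges = [(d["weight"], d["cost"]) for _, _, d in g.graph.edges(data=True)]
        for (wa, ca) in edges:
            for (wb, cb) in edges:
                if wa > wb:
                    assert ca < cb

    def test_threshold_filters_edges(self):
        m = matrix_from_edges(3, [(0, 1, 0.9), (1, 2, 0.3)])
        g = build_path_graph(m, 0.5)
        assert g.graph.has_edge(0, 1)
        assert not g.graph.has_edge(1, 2)

    def test_all_filtered_warns_not_raises(self):
        m = matrix_from_edges(3, [(0, 1, 0.2)])
        with pytest.warns(UserWarning, match="filtered out"):
            g = build_path_graph(m, 0.9)
        assert g.graph.number_of_edges() == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_path_graph(matrix_from_edges(2, []), 1.0)


class TestShortestPaths:
    def chain(self):
        return build_path_graph(
            matrix_from_edges(3, [(0, 1, 0.9), (1, 2, 0.9)]), 0.5)

    def test_unique_chain_path(self):
        ps = shortest_paths(self.chain(), [0], [2], k=1)
        assert [p.nodes for p in ps.paths] == [(0, 1, 2)]

    def test_disconnected_sink_yields_empty_entry(self):
        g = build_path_graph(matrix_from_edges(3, [(0, 1, 0.9)]), 0.5)
        ps = shortest_paths(g, [0], [2], k=2)
        assert ps.paths == []
        assert ps.by_pair[(0, 2)] == []

    def test_unknown_node_named(self):
        with pytest.raises(ValueError, match="9"):
            shortest_paths(self.chain(), [0], [9])

    def test_overlapping_sources_sinks_rejected(self):
        with pytest.raises(ValueError):
            shortest_paths(self.chain(), [0, 1], [1, 2])

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_k_shortest_matches_enumeration(self, seed):
        """On random <=6-node graphs, k=1 equals the cheapest enumerated
        simple path and k=3 matches the 3 cheapest."""
        rng = np.random.default_rng(seed)
        n = 6
        w = rng.uniform(size=(n, n)) * (rng.uniform(size=(n, n)) < 0.6)
        np.fill_diagonal(w, 0.0)
        g = build_path_graph(InteractionMatrix(w), 0.2)
        s, t = 0, n - 1
        expected = enumerate_simple_paths(g.graph, s, t)
        if not expected:
            assert shortest_paths(g, [s], [t], 3).paths == []
            return
        ps1 = shortest_paths(g, [s], [t], k=1)
        assert ps1.paths[0].cost == pytest.approx(expected[0][0], abs=1e-9)
        ps3 = shortest_paths(g, [s], [t], k=3)
        for got, (cost, _) in zip(ps3.paths, expected[:3]):
            assert got.cost == pytest.approx(cost, abs=1e-9)

    def test_k1_cost_lower_bounds_suboptimal_paths(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.3, 1.0, size=(5, 5))
        np.fill_diagonal(w, 0.0)
        g = build_path_graph(InteractionMatrix(w), 0.3)
        ps = shortest_paths(g, [0], [4], k=4)
        costs = [p.cost for p in ps.by_pair[(0, 4)]]
        assert costs == sorted(costs)

    def test_adding_edge_never_increases_cost(self):
        """Shortest-path monotonicity under edge insertion."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            w = rng.uniform(size=(5, 5)) * (rng.uniform(size=(5, 5)) < 0.5)
            np.fill_diagonal(w, 0.0)
            base = build_path_graph(InteractionMatrix(w), 0.2)
            zeros = np.argwhere((w < 0.2) & ~np.eye(5, dtype=bool))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = 0.95
            richer = build_path_graph(InteractionMatrix(w2), 0.2)
            for s, t in [(0, 4), (1, 3)]:
                p_base = shortest_paths(base, [s], [t], 1).by_pair[(s, t)]
                p_rich = shortest_paths(richer, [s], [t], 1).by_pair[(s, t)]
                if p_base:
                    assert p_rich, "adding an edge cannot disconnect"
                    assert p_rich[0].cost <= p_base[0].cost + 1e-9


class TestPathResidueFrequency:
    def test_single_path_counts_each_node_once(self):
        g = build_path_graph(
            matrix_from_edges(3, [(0, 1, 0.9), (1, 2, 0.9)]), 0.5)
        ps = shortest_paths(g, [0], [2], 1)
        freq = path_residue_frequency(ps, 3)
        assert list(freq) == [1, 1, 1]

    def test_absent_node_counts_zero(self):
        g = build_path_graph(
            matrix_from_edges(4, [(0, 1, 0.9), (1, 3, 0.9)]), 0.5)
        ps = shortest_paths(g, [0], [3], 1)
        assert path_residue_frequency(ps, 4)[2] == 0

    def test_matches_brute_membership_count(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(0.3, 1.0, size=(6, 6))
        np.fill_diagonal(w, 0.0)
        g = build_path_graph(InteractionMatrix(w), 0.3)
        ps = shortest_paths(g, [0, 1], [4, 5], k=2)
        freq = path_residue_frequency(ps, 6)
        for node in range(6):
            expected = sum(node in p.nodes for p in ps.paths)
            assert freq[node] == expected

    def test_empty_pathset_rejected(self):
        g = build_path_graph(matrix_from_edges(3, [(0, 1, 0.9)]), 0.5)
        ps = shortest_paths(g, [0], [2], 1)
        with pytest.raises(ValueError):
            path_residue_frequency(ps)


class TestNodeCentrality:
    def test_chain_middle_node_only(self):
        g = build_path_graph(
            matrix_from_edges(3, [(0, 1, 0.9), (1, 2, 0.9)]), 0.5)
        c = node_centrality(g)
        assert c[1] > 0
        assert c[0] == 0 and c[2] == 0

    def test_symmetric_complete_graph_equal_centralities(self):
        n = 4
        w = np.full((n, n), 0.8)
        np.fill_diagonal(w, 0.0)
        c = node_centrality(build_path_graph(InteractionMatrix(w), 0.5))
        np.testing.assert_allclose(c, c.iloc[0])

    def test_matches_brute_force_shortest_path_counting(self):
        """Betweenness on a <=6-node graph vs exhaustive counting of
        minimum-cost simple paths through each node."""
        rng = np.random.default_rng(8)
        n = 5
        w = rng.uniform(size=(n, n)) * (rng.uniform(size=(n, n)) < 0.7)
        np.fill_diagonal(w, 0.0)
        g = build_path_graph(InteractionMatrix(w), 0.2)
        got = node_centrality(g)

        counts = np.zeros(n)
        for s, t in permutations(range(n), 2):
            paths = enumerate_simple_paths(g.graph, s, t)
            if not paths:
                continue
            best = paths[0][0]
            shortest = [p for c, p in paths if abs(c - best) < 1e-12]
            for node in range(n):
                if node in (s, t):
                    continue
                through = sum(node in p for p in shortest)
                counts[node] += through / len(shortest)
        expected = counts / ((n - 1) * (n - 2))
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-9)

    def test_empty_graph_rejected(self):
        g = PathGraph(nx.DiGraph(), 0.5, "neg_log")
        with pytest.raises(ValueError):
            node_centrality(g)


def test_pathset_json_round_trip(tmp_path):
    import json

    g = build_path_graph(
        matrix_from_edges(3, [(0, 1, 0.9), (1, 2, 0.9)]), 0.5)
    ps = shortest_paths(g, [0], [2], 1)
    ps.to_json(tmp_path / "paths.json")
    payload = json.loads((tmp_path / "paths.json").read_text())
    assert payload["paths"][0]["nodes"] == [0, 1, 2]
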