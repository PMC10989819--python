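"""Network inference, variance refinement, edge ranking and export."""

import numpy as np
import pytest

from micromarkers import (Adjacency, EdgeList, export_graph,
                          generate_network_data, hub_report, infer_adjacency,
                          refine_adjacency, top_edges)
from micromarkers.network import read_edge_tsv, to_digraph


def hand_refine(M):
    """Independent oracle: row-wise variance scaling of the adjacency."""
    p = M.shape[0]
    out = np.zeros_like(M)
    for i in range(p):
        off = [M[i, j] for j in range(p) if j != i]
        mu = sum(off) / len(off)
        var = sum((v - mu) ** 2 for v in off) / len(off)
        for j in range(p):
            if j != i:
                out[i, j] = M[i, j] * var
    return out


def random_adjacency(rng, p=5):
    M = rng.random((p, p))
    np.fill_diagonal(M, 0.0)
    return Adjacency([f"n{i}" for i in range(p)], M)


class TestRefineAdjacency:
    def test_three_node_hand_example(self):
        adj = Adjacency(["a", "b", "c"],
                        np.array([[0.0, 0.2, 0.4],
                                  [0.0, 0.0, 0.0],
                                  [0.0, 0.0, 0.0]]))
        out = refine_adjacency(adj)
        # off-diagonal (0.2, 0.4): population variance 0.01
        np.testing.assert_allclose(out.M[0], [0.0, 0.002, 0.004], atol=1e-15)

    def test_matches_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            adj = random_adjacency(rng)
            np.testing.assert_allclose(refine_adjacency(adj).M,
                                       hand_refine(adj.M), atol=1e-12)

    def test_equal_offdiagonal_row_maps_to_zero(self):
        adj = Adjacency(["a", "b", "c"],
                        np.array([[0.0, 0.3, 0.3],
                                  [0.1, 0.0, 0.2],
                                  [0.0, 0.0, 0.0]]))
        np.testing.assert_array_equal(refine_adjacency(adj).M[0], 0.0)

    def test_row_scaling_is_cubic(self):
        rng = np.random.default_rng(1)
        adj = random_adjacency(rng)
        scaled = Adjacency(adj.feature_ids, adj.M * 2.0)
        np.testing.assert_allclose(refine_adjacency(scaled).M,
                                   8.0 * refine_adjacency(adj).M, atol=1e-12)

    def test_divide_mode_inverts_scaling(self):
        rng = np.random.default_rng(2)
        adj = random_adjacency(rng)
        mult = refine_adjacency(adj, mode="multiply")
        div = refine_adjacency(adj, mode="divide")
        # multiply then divide by var^2 recovers M on non-degenerate rows
        p = len(adj.feature_ids)
        off = ~np.eye(p, dtype=bool)
        var = np.array([adj.M[i][off[i]].var() for i in range(p)])
        np.testing.assert_allclose(mult.M / var[:, None] ** 2, div.M * 1.0,
                                   atol=1e-10)


class TestInferAdjacency:
    def test_planted_chain_edge_dominates_target_column(self):
        x = generate_network_data([(0, 1, 1.0)], n_features=4,
                                  n_samples=1000, noise_sd=0.1, seed=1)
        adj = infer_adjacency(x, n_trees=200, seed=1)
        assert adj.M[0, 1] == adj.M[:, 1].max()
        assert adj.M[0, 1] > 0.5  # normalised column: dominant parent

    def test_diagonal_is_zero(self):
        x = np.random.default_rng(0).normal(size=(50, 5))
        adj = infer_adjacency(x, n_trees=50, seed=0)
        assert np.diagonal(adj.M).sum() == 0.0

    def test_constant_target_column_zeroed_with_warning(self, caplog):
        x = np.random.default_rng(0).normal(size=(40, 4))
        x[:, 2] = 1.0
        with caplog.at_level("WARNING"):
            adj = infer_adjacency(x, n_trees=30, seed=0)
        assert (adj.M[:, 2] == 0.0).all()
        assert "constant" in caplog.text

    def test_columns_normalised_to_unit_sum(self):
        x = np.random.default_rng(3).normal(size=(60, 5))
        adj = infer_adjacency(x, n_trees=50, seed=3)
        np.testing.assert_allclose(adj.M.sum(axis=0), 1.0, atol=1e-9)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            infer_adjacency(np.random.default_rng(0).normal(size=(50, 2)))


class TestTopEdges:
    def test_availability_bound(self):
        M = np.zeros((4, 4))
        M[0, 1], M[1, 2], M[2, 3], M[0, 2], M[3, 0] = 0.5, 0.4, 0.3, 0.2, 0.1
        edges = top_edges(Adjacency(list("abcd"), M), n=100)
        assert len(edges) == 5

    def test_descending_weights_with_lexicographic_ties(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = M[0, 2] = 0.5
        edges = top_edges(Adjacency(list("abc"), M), n=3)
        assert edges.edges == [("a", "b", 0.5), ("a", "c", 0.5),
                               ("b", "a", 0.5)]

    def test_star_source_total_degree(self):
        M = np.zeros((7, 7))
        M[0, 1:] = np.linspace(0.7, 0.2, 6)
        edges = top_edges(Adjacency([f"n{i}" for i in range(7)], M), n=100)
        assert edges.total_degree("n0") == 6
        assert edges.out_degree["n0"] == 6

    def test_all_zero_matrix_yields_empty_list(self, caplog):
        with caplog.at_level("WARNING"):
            edges = top_edges(Adjacency(list("abc"), np.zeros((3, 3))))
        assert len(edges) == 0


class TestHubReport:
    def test_empty_edge_list_empty_report(self):
        report = hub_report(EdgeList(edges=[]))
        assert report == {5: [], 10: []}

    def test_six_distinct_partners_meets_threshold_five(self):
        edges = [("x", f"t{i}", 0.9 - 0.1 * i) for i in range(3)]
        edges += [(f"s{i}", "x", 0.5 - 0.1 * i) for i in range(3)]
        report = hub_report(EdgeList(edges=sorted(edges, key=lambda e: -e[2])))
        assert ("x", 6) in report[5]
        assert report[10] == []

    def test_reciprocal_edges_count_partners_once(self):
        pairs = [("x", f"p{i}") for i in range(4)]
        edges = [(a, b, 0.5) for a, b in pairs] + [(b, a, 0.5) for a, b in pairs]
        el = EdgeList(edges=edges)
        assert el.total_degree("x") == 4
        assert hub_report(el)[5] == []


class TestExportGraph:
    @pytest.fixture
    def edges(self):
        return EdgeList(edges=[("a", "b", 0.123456789123), ("b", "c", 0.1)])

    def test_tsv_roundtrip_preserves_edges(self, tmp_path, edges):
        path = tmp_path / "edges.tsv"
        export_graph(edges, path, format="tsv")
        back = read_edge_tsv(path)
        assert [(s, t) for s, t, _ in back.edges] == [("a", "b"), ("b", "c")]
        assert back.edges[0][2] == pytest.approx(0.123456789123, abs=1e-9)

    def test_graphml_roundtrip(self, tmp_path, edges):
        import networkx as nx
        path = tmp_path / "g.graphml"
        export_graph(edges, path, format="graphml")
        g = nx.read_graphml(path)
        assert g["a"]["b"]["weight"] == pytest.approx(0.123456789123, abs=1e-9)
        assert g.nodes["b"]["degree"] == 2

    def test_empty_edge_list_valid_files(self, tmp_path):
        empty = EdgeList(edges=[])
        export_graph(empty, tmp_path / "e.tsv", format="tsv")
        export_graph(empty, tmp_path / "e.graphml", format="graphml")
        assert read_edge_tsv(tmp_path / "e.tsv").edges == []

    def test_digraph_is_directed_with_weights(self, edges):
        g = to_digraph(edges)
        assert g.is_directed()
        assert g.has_edge("a", "b") and not g.has_edge("c", "b")
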