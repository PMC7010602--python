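"""Cluster distances, lineage-graph construction and transition genes."""

import numpy as np
import pytest

from calista.burst_model import TwoStateParams
from calista.clustering import assignment_from_labels
from calista.lineage import (
    ClusterDistances,
    Edge,
    LineageGraph,
    build_graph,
    build_graph_timed,
    cluster_distances,
    direct_edges,
    edit_graph,
    transition_genes,
)
from calista.synthetic import simulate_clusters


def distances_from_matrix(D):
    D = np.asarray(D, dtype=float)
    return ClusterDistances(S=np.zeros_like(D), S_hat=D.copy(), D=D)


class TestClusterDistances:
    def test_hand_computed_on_tiny_fixture(self, tiny_table):
        # 5 cells, 2 genes, hand-assigned labels; oracle recomputes every
        # table lookup explicitly
        from calista.preprocess import ExpressionMatrix

        values = np.array([[3, 100], [5, 120], [90, 4], [110, 2], [100, 8]])
        mat = ExpressionMatrix(
            values=values.astype(float),
            cell_ids=list("abcde"),
            gene_names=["g1", "g2"],
            scaled=True,
        )
        labels = np.array([1, 1, 2, 2, 2])
        assignment = assignment_from_labels(mat, labels, tiny_table)
        dist = cluster_distances(assignment, mat, tiny_table)

        # oracle: per-(cluster, gene) argmax over the 4 grid points, then
        # per-cell-per-gene normalized cross-likelihoods
        P = tiny_table.log_pmf
        members = {1: [0, 1], 2: [2, 3, 4]}
        best_idx = {}
        for k, rows in members.items():
            for g in range(2):
                lls = [sum(P[i, values[r, g]] for r in rows) for i in range(4)]
                best_idx[(k, g)] = int(np.argmax(lls))
        S = np.zeros((2, 2))
        for k, rows in members.items():
            for j in range(1, 3):
                tot = sum(
                    P[best_idx[(j, g)], values[r, g]] for r in rows for g in range(2)
                )
                S[k - 1, j - 1] = tot / len(rows) / 2
        assert np.allclose(dist.S, S)
        assert np.allclose(dist.S_hat, np.diag(S)[:, None] - S)

    def test_distance_matrix_symmetric_zero_diagonal(self, three_cluster_data, table):
        mat, truth = three_cluster_data
        dist = cluster_distances(assignment_from_labels(mat, truth, table), mat)
        assert np.allclose(dist.D, dist.D.T)
        assert np.allclose(np.diag(dist.D), 0)
        assert np.all(dist.S_hat >= -1e-9)

    def test_same_parameter_clusters_have_near_zero_distance(self, table):
        params = [[TwoStateParams(1.0, 1.0, 40.0)] * 10] * 2
        mat, truth = simulate_clusters(2, 10, 200, params, seed=21)
        dist = cluster_distances(assignment_from_labels(mat, truth, table), mat)
        assert dist.D[0, 1] < 0.05


class TestBuildGraph:
    def test_two_clusters_single_edge(self):
        g = build_graph(distances_from_matrix([[0, 1.5], [1.5, 0]]))
        assert g.to_edge_list() == [(1, 2, 1.5, False)]

    def test_chain_distances_give_path(self):
        D = np.full((4, 4), 10.0)
        np.fill_diagonal(D, 0)
        for i in range(3):
            D[i, i + 1] = D[i + 1, i] = 1.0 + 0.1 * i
        g = build_graph(distances_from_matrix(D))
        assert sorted(e.key() for e in g.edges) == [(1, 2), (2, 3), (3, 4)]

    def test_tied_distances_break_lexicographically(self):
        D = np.full((3, 3), 2.0)
        np.fill_diagonal(D, 0)
        g = build_graph(distances_from_matrix(D), ensure_connected=False)
        # all pairs tie; (1,2) then (1,3) suffice for min degree 1
        assert [e.key() for e in g.edges] == [(1, 2), (1, 3)]

    def test_minimum_degree_at_least_one(self):
        rng = np.random.default_rng(3)
        A = rng.random((6, 6))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        g = build_graph(distances_from_matrix(D))
        assert min(g.degree(n) for n in g.nodes) >= 1


class TestBuildGraphTimed:
    @staticmethod
    def _assignment(table, theta_ts, cells=60, genes=6, seed=0):
        params = [[TwoStateParams(1.0, 1.0, t)] * genes for t in theta_ts]
        mat, truth = simulate_clusters(len(theta_ts), genes, cells, params, seed=seed)
        return mat, assignment_from_labels(mat, truth, table)

    def test_directed_chain_from_time_modes(self, table):
        mat, assignment = self._assignment(table, [5.0, 40.0, 150.0])
        times = np.repeat([0.0, 1.0, 2.0], 60)
        g = build_graph_timed(
            cluster_distances(assignment, mat), assignment, times
        )
        assert {(e.source, e.target) for e in g.edges} == {(1, 2), (2, 3)}
        assert all(e.directed for e in g.edges)

    def test_shared_time_mode_gives_bifurcation(self, table):
        # clusters 2 and 3 share stage mode 2 but carry 10% stage-1
        # stragglers, so their early-time cutoff points below the sibling
        times = np.repeat([1.0, 2.0, 2.0], 60)
        times[60:66] = 1.0
        times[120:126] = 1.0
        mat, assignment = self._assignment(table, [30.0, 60.0, 150.0])
        g = build_graph_timed(
            cluster_distances(assignment, mat), assignment, times
        )
        assert {(e.source, e.target) for e in g.edges} == {(1, 2), (1, 3)}

    def test_start_cluster_has_no_incoming_edge(self, table):
        mat, assignment = self._assignment(table, [5.0, 40.0, 150.0])
        times = np.repeat([0.0, 1.0, 2.0], 60)
        g = build_graph_timed(cluster_distances(assignment, mat), assignment, times)
        assert all(e.target != 1 for e in g.edges)


class TestDirectEdges:
    def path_graph(self):
        return LineageGraph(
            nodes=[1, 2, 3],
            edges=[Edge(2, 1, 1.0), Edge(2, 3, 1.0)],
        )

    def test_orients_by_pseudotime(self):
        g = direct_edges(self.path_graph(), {1: 0.0, 2: 0.5, 3: 1.0})
        assert {(e.source, e.target) for e in g.edges} == {(1, 2), (2, 3)}
        assert all(e.directed for e in g.edges)

    def test_equal_pseudotimes_left_undirected(self):
        with pytest.warns(UserWarning, match="equal pseudotimes"):
            g = direct_edges(self.path_graph(), {1: 0.0, 2: 0.5, 3: 0.5})
        flags = {e.key(): e.directed for e in g.edges}
        assert flags[(1, 2)] and not flags[(2, 3)]

    def test_idempotent_on_directed_graph(self):
        t = {1: 0.0, 2: 0.5, 3: 1.0}
        once = direct_edges(self.path_graph(), t)
        twice = direct_edges(once, t)
        assert once.to_edge_list() == twice.to_edge_list()


class TestEditGraph:
    def base(self):
        return LineageGraph(nodes=[1, 2, 3], edges=[Edge(1, 2, 1.0)])

    def test_add_then_remove_restores_graph(self):
        g = self.base()
        out = edit_graph(edit_graph(g, add=[(2, 3)]), remove=[(2, 3)])
        assert out.to_edge_list() == g.to_edge_list()

    def test_duplicate_add_rejected(self):
        with pytest.raises(ValueError, match="already present"):
            edit_graph(self.base(), add=[(2, 1)])

    def test_removing_missing_edge_rejected(self):
        with pytest.raises(ValueError, match="not in graph"):
            edit_graph(self.base(), remove=[(1, 3)])

    def test_isolating_removal_warns_but_succeeds(self):
        with pytest.warns(UserWarning, match="isolated"):
            out = edit_graph(self.base(), remove=[(1, 2)])
        assert out.edges == []


class TestStartClusterAndExport:
    def test_marker_start_detection_both_directions(self, table):
        from calista.lineage import start_cluster_from_markers

        params = [[TwoStateParams(1.0, 1.0, t)] * 4 for t in (10.0, 150.0)]
        mat, truth = simulate_clusters(2, 4, 50, params, seed=13)
        assignment = assignment_from_labels(mat, truth, table)
        assert start_cluster_from_markers(assignment, mat, ["gene_0"], highest=True) == 2
        assert start_cluster_from_markers(assignment, mat, ["gene_0"], highest=False) == 1

    def test_graphml_roundtrip(self, tmp_path):
        import networkx as nx

        from calista.lineage import write_graphml

        g = LineageGraph(
            nodes=[1, 2, 3],
            edges=[Edge(1, 2, 0.5, directed=True), Edge(2, 3, 1.5, directed=True)],
            pseudotimes={1: 0.0, 2: 0.5, 3: 1.0},
        )
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 3 and back.number_of_edges() == 2


class TestTransitionGenes:
    def test_identical_gene_scores_near_zero(self, table):
        params = [[TwoStateParams(1.0, 1.0, 40.0)] * 4] * 2
        mat, truth = simulate_clusters(2, 4, 150, params, seed=31)
        assignment = assignment_from_labels(mat, truth, table)
        res = transition_genes(assignment, mat, table, (1, 2))
        # same generating parameters: pooling costs essentially nothing
        assert np.all(res.score < 5.0)

    def test_scores_nonnegative_on_random_labelings(self, three_cluster_data, table):
        mat, _ = three_cluster_data
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 4, size=mat.n_cells)
        assignment = assignment_from_labels(mat, labels, table)
        res = transition_genes(assignment, mat, table, (1, 3))
        assert np.all(res.score >= 0)

    def test_selection_is_prefix_of_ranking(self, three_cluster_data, table):
        mat, truth = three_cluster_data
        assignment = assignment_from_labels(mat, truth, table)
        res = transition_genes(assignment, mat, table, (1, 2), threshold=0.5)
        assert res.selected.tolist() == res.order[: res.selected.size].tolist()

    def test_planted_differential_genes_selected(self, table):
        # only genes 0-2 differ between the clusters
        base = [TwoStateParams(1.0, 1.0, 40.0)] * 7
        p1 = [TwoStateParams(1.0, 1.0, 10.0)] * 3 + base
        p2 = [TwoStateParams(1.0, 1.0, 150.0)] * 3 + base
        mat, truth = simulate_clusters(2, 10, 100, [p1, p2], seed=41)
        assignment = assignment_from_labels(mat, truth, table)
        res = transition_genes(assignment, mat, table, (1, 2), threshold=0.5)
        assert sorted(res.selected.tolist()) == [0, 1, 2]
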