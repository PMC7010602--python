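"""Cluster pseudotimes, cell-to-edge allocation and path ordering."""

import numpy as np
import pytest

from calista.burst_model import TwoStateParams
from calista.clustering import assignment_from_labels
from calista.lineage import Edge, LineageGraph
from calista.pseudotime import (
    assign_cells_to_edges,
    cluster_pseudotimes_from_distances,
    cluster_pseudotimes_from_times,
    likelihood_landscape,
    order_path,
)
from calista.pseudotime import _edge_max
from calista.synthetic import simulate_clusters


@pytest.fixture(scope="module")
def chain_setup(table):
    """Three-state chain: matrix, fitted assignment, directed graph."""
    params = [[TwoStateParams(1.0, 1.0, t)] * 8 for t in (10.0, 50.0, 150.0)]
    mat, truth = simulate_clusters(3, 8, 80, params, seed=17)
    assignment = assignment_from_labels(mat, truth, table)
    graph = LineageGraph(
        nodes=[1, 2, 3],
        edges=[Edge(1, 2, 1.0, directed=True), Edge(2, 3, 1.0, directed=True)],
    )
    t_map = {1: 0.0, 2: 0.5, 3: 1.0}
    return mat, assignment, graph, t_map


class TestClusterPseudotimesFromTimes:
    @staticmethod
    def _assignment_with(table, times_len):
        params = [[TwoStateParams(1.0, 1.0, 30.0)] * 3]
        mat, truth = simulate_clusters(1, 3, times_len, params, seed=2)
        return assignment_from_labels(mat, truth, table)

    def test_mode_over_max(self, table):
        a = self._assignment_with(table, 3)
        assert cluster_pseudotimes_from_times(a, np.array([0.0, 0.0, 5.0])) == {1: 0.0}

    def test_all_max_time_cluster_gets_one(self, table):
        a = self._assignment_with(table, 3)
        assert cluster_pseudotimes_from_times(a, np.array([5.0, 5.0, 5.0])) == {1: 1.0}

    def test_fractional_stages(self, table):
        a = self._assignment_with(table, 4)
        t = cluster_pseudotimes_from_times(a, np.array([2.0, 2.5, 2.0, 3.0]))
        assert t[1] == pytest.approx(2.0 / 3.0)

    def test_multimodal_tie_uses_smallest_with_warning(self, table):
        a = self._assignment_with(table, 4)
        with pytest.warns(UserWarning, match="multimodal"):
            t = cluster_pseudotimes_from_times(a, np.array([1.0, 1.0, 4.0, 4.0]))
        assert t[1] == pytest.approx(0.25)


class TestClusterPseudotimesFromDistances:
    def test_equal_edges_on_path(self):
        g = LineageGraph(
            nodes=[1, 2, 3], edges=[Edge(1, 2, 2.0), Edge(2, 3, 2.0)]
        )
        t = cluster_pseudotimes_from_distances(g, None, start=1)
        assert t == {1: 0.0, 2: 0.5, 3: 1.0}

    def test_star_graph_leaf_ratio(self):
        g = LineageGraph(
            nodes=[1, 2, 3], edges=[Edge(1, 2, 1.0), Edge(1, 3, 3.0)]
        )
        t = cluster_pseudotimes_from_distances(g, None, start=1)
        assert t[2] == pytest.approx(1 / 3) and t[3] == 1.0 and t[1] == 0.0

    def test_disconnected_graph_rejected(self):
        g = LineageGraph(nodes=[1, 2, 3], edges=[Edge(1, 2, 1.0)])
        with pytest.raises(ValueError, match="disconnected"):
            cluster_pseudotimes_from_distances(g, None, start=1)


class TestEdgeMax:
    def test_constant_interpolant_resolves_to_midpoint(self):
        t, v = _edge_max(-5.0, -5.0, 0.2, 0.6, 100)
        assert t == pytest.approx(0.4) and v == -5.0

    def test_linear_maximum_at_endpoint(self):
        t, v = _edge_max(-10.0, -2.0, 0.0, 1.0, 100)
        assert t == 1.0 and v == -2.0
        t, v = _edge_max(-2.0, -10.0, 0.0, 1.0, 100)
        assert t == 0.0 and v == -2.0


class TestAssignCellsToEdges:
    def test_pseudotime_within_edge_interval(self, chain_setup):
        mat, assignment, graph, t_map = chain_setup
        out = assign_cells_to_edges(mat, assignment, graph, t_map)
        for i in range(mat.n_cells):
            lo = min(t_map[out.edge_source[i]], t_map[out.edge_target[i]])
            hi = max(t_map[out.edge_source[i]], t_map[out.edge_target[i]])
            assert lo <= out.pseudotime[i] <= hi

    def test_assigned_edge_incident_to_own_cluster(self, chain_setup):
        mat, assignment, graph, t_map = chain_setup
        out = assign_cells_to_edges(mat, assignment, graph, t_map)
        for i in range(mat.n_cells):
            assert assignment.labels[i] in (out.edge_source[i], out.edge_target[i])

    def test_undirected_graph_rejected(self, chain_setup):
        mat, assignment, _, t_map = chain_setup
        g = LineageGraph(nodes=[1, 2, 3], edges=[Edge(1, 2, 1.0), Edge(2, 3, 1.0)])
        with pytest.raises(ValueError, match="undirected"):
            assign_cells_to_edges(mat, assignment, g, t_map)

    def test_isolated_cluster_keeps_cluster_time(self, chain_setup, table):
        mat, assignment, _, t_map = chain_setup
        g = LineageGraph(nodes=[1, 2, 3], edges=[Edge(1, 2, 1.0, directed=True)])
        with pytest.warns(UserWarning, match="isolated"):
            out = assign_cells_to_edges(mat, assignment, g, t_map)
        cells3 = np.where(assignment.labels == 3)[0]
        assert np.all(out.pseudotime[cells3] == t_map[3])
        assert np.all(out.edge_source[cells3] == -1)

    def test_grid_resolution_does_not_change_order(self, chain_setup):
        # the interpolant's argmax sits at an endpoint (or midpoint on
        # ties), so any monotone reparameterization — here realized as a
        # different grid resolution — yields the same cell order
        mat, assignment, graph, t_map = chain_setup
        coarse = assign_cells_to_edges(mat, assignment, graph, t_map, n_grid=7)
        fine = assign_cells_to_edges(mat, assignment, graph, t_map, n_grid=500)
        path = [1, 2, 3]
        assert order_path(coarse, path)["cell_id"].tolist() == (
            order_path(fine, path)["cell_id"].tolist()
        )


class TestOrderPath:
    def test_cells_sorted_by_pseudotime(self, chain_setup):
        mat, assignment, graph, t_map = chain_setup
        out = assign_cells_to_edges(mat, assignment, graph, t_map)
        df = order_path(out, [1, 2, 3])
        assert np.all(np.diff(df["pseudotime"].to_numpy()) >= 0)

    def test_shared_prefix_cells_appear_in_both_paths(self, table):
        # bifurcation 1 -> 2 -> {3, 4}: edge (1,2) cells are in both paths
        params = [[TwoStateParams(1.0, 1.0, t)] * 8 for t in (10.0, 40.0, 100.0, 250.0)]
        mat, truth = simulate_clusters(4, 8, 50, params, seed=19)
        assignment = assignment_from_labels(mat, truth, table)
        graph = LineageGraph(
            nodes=[1, 2, 3, 4],
            edges=[
                Edge(1, 2, 1.0, directed=True),
                Edge(2, 3, 1.0, directed=True),
                Edge(2, 4, 1.0, directed=True),
            ],
        )
        t_map = {1: 0.0, 2: 0.4, 3: 1.0, 4: 1.0}
        out = assign_cells_to_edges(mat, assignment, graph, t_map)
        a = order_path(out, [1, 2, 3])
        b = order_path(out, [1, 2, 4])
        shared = out.to_frame().query("edge_source == 1 and edge_target == 2")
        assert set(shared["cell_id"]) <= set(a["cell_id"])
        assert set(shared["cell_id"]) <= set(b["cell_id"])

    def test_anti_directional_path_rejected(self, chain_setup):
        mat, assignment, graph, t_map = chain_setup
        out = assign_cells_to_edges(mat, assignment, graph, t_map)
        with pytest.raises(ValueError, match="not in lineage graph"):
            order_path(out, [3, 2, 1])


class TestLikelihoodLandscape:
    def test_matches_stored_cell_likelihoods(self, chain_setup):
        mat, assignment, _, _ = chain_setup
        df = likelihood_landscape(mat, assignment)
        expected = -assignment.cell_loglik[
            np.arange(mat.n_cells), assignment.labels - 1
        ]
        assert np.allclose(df["neg_loglik"], expected)

    def test_duplicate_cells_identical_values(self, table):
        params = [[TwoStateParams(1.0, 1.0, 40.0)] * 5]
        mat, truth = simulate_clusters(1, 5, 30, params, seed=23)
        mat.values[1] = mat.values[0]
        assignment = assignment_from_labels(mat, truth, table)
        df = likelihood_landscape(mat, assignment)
        assert df["neg_loglik"][0] == df["neg_loglik"][1]

    def test_embedding_passthrough_validated(self, chain_setup):
        mat, assignment, _, _ = chain_setup
        with pytest.raises(ValueError, match="embedding"):
            likelihood_landscape(mat, assignment, embedding=np.zeros((3, 2)))
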