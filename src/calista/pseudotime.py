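"""Pseudotemporal ordering of cells along the lineage graph.

Cluster pseudotimes come either from capture times (mode over member
cells, normalized by the largest time) or from cumulative cluster
distances to a start cluster.  Each cell is then allocated to one of the
transition edges incident to its cluster by maximizing the linear
interpolation of its per-cluster log-likelihoods over the edge's
pseudotime interval; the argmax position is the cell's pseudotime.
Because the interpolant is linear, the maximum sits at an endpoint
whenever the two likelihoods differ; the per-cell likelihood difference
Λ_target − Λ_source is retained as the within-edge ordering key, which is
the information the interpolation actually carries (any strictly monotone
reparameterization of the interpolant yields the same cell order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .lineage import ClusterDistances, LineageGraph
from .preprocess import ExpressionMatrix

__all__ = [
    "CellOrdering",
    "cluster_pseudotimes_from_times",
    "cluster_pseudotimes_from_distances",
    "assign_cells_to_edges",
    "order_path",
    "likelihood_landscape",
]


@dataclass
class CellOrdering:
    """Per-cell edge assignment and pseudotime.

    ``edge_source``/``edge_target`` are 1-based cluster ids (-1 for cells
    of isolated clusters); ``pseudotime`` lies within the assigned edge's
    interval; ``interp_loglik`` is the maximized interpolated likelihood
    and ``order_key`` the within-edge tie-break Λ_target − Λ_source.
    """

    cell_ids: list[str]
    labels: np.ndarray  # (N,) cluster of each cell
    edge_source: np.ndarray  # (N,) int
    edge_target: np.ndarray  # (N,) int
    pseudotime: np.ndarray  # (N,) float in [0, 1]
    interp_loglik: np.ndarray  # (N,)
    order_key: np.ndarray  # (N,) Λ_target − Λ_source on the assigned edge
    cluster_pseudotimes: dict[int, float] = field(default_factory=dict)
    graph: LineageGraph | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "cluster": self.labels,
                "edge_source": self.edge_source,
                "edge_target": self.edge_target,
                "pseudotime": self.pseudotime,
                "interp_loglik": self.interp_loglik,
            }
        )


def cluster_pseudotimes_from_times(
    assignment: ClusterAssignment, times: np.ndarray
) -> dict[int, float]:
    """t_k = mode(member capture times) / max(all times), in [0, 1].

    Multimodal ties resolve to the smallest modal value with a warning.
    """
    times = np.asarray(times, dtype=float)
    t_max = times.max()
    if t_max <= 0:
        raise ValueError("largest capture time must be positive")
    out = {}
    for k in range(1, assignment.K + 1):
        vals = times[assignment.members(k)]
        uniq, counts = np.unique(vals, return_counts=True)
        top = np.where(counts == counts.max())[0]
        if top.size > 1:
            warnings.warn(f"cluster {k}: multimodal times; using smallest mode")
        out[k] = float(uniq[top[0]]) / t_max
    return out


def cluster_pseudotimes_from_distances(
    graph: LineageGraph, dist: ClusterDistances, start: int
) -> dict[int, float]:
    """Cumulative cluster distance from the start, normalized to [0, 1]."""
    import networkx as nx

    if start not in graph.nodes:
        raise ValueError(f"start cluster {start} not in graph")
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for e in graph.edges:
        g.add_edge(e.source, e.target, distance=e.distance)
    if not nx.is_connected(g):
        raise ValueError("lineage graph is disconnected")
    lengths = nx.single_source_dijkstra_path_length(g, start, weight="distance")
    t_max = max(lengths.values())
    if t_max == 0:
        return dict.fromkeys(graph.nodes, 0.0)
    return {k: lengths[k] / t_max for k in graph.nodes}


def _edge_max(
    lam_a: float, lam_b: float, t_a: float, t_b: float, n_grid: int
) -> tuple[float, float]:
    """Maximize the linear interpolant of (Λ_a, Λ_b) over a pseudotime grid.

    Returns (pseudotime, value).  A constant interpolant (Λ_a = Λ_b) ties
    on every grid point and resolves to the interval midpoint.
    """
    if t_a == t_b or lam_a == lam_b:
        return 0.5 * (t_a + t_b), max(lam_a, lam_b)
    grid = np.linspace(t_a, t_b, n_grid)
    vals = lam_a + (grid - t_a) / (t_b - t_a) * (lam_b - lam_a)
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])


def assign_cells_to_edges(
    mat: ExpressionMatrix,
    assignment: ClusterAssignment,
    graph: LineageGraph,
    t_map: dict[int, float],
    n_grid: int = 100,
) -> CellOrdering:
    """Maximum-likelihood allocation of every cell to an incident edge.

    A cell in cluster k competes across all directed edges j→k and k→l
    incident to its cluster; for each edge the linear interpolation of
    (Λ_source(n), Λ_target(n)) is maximized over ``n_grid`` pseudotime
    points spanning the edge, and the cell takes the best edge and the
    argmax pseudotime.  Equal-likelihood edge ties go to incoming edges
    (then edge order); cells of isolated clusters keep t = t_k with no
    edge.
    """
    undirected = [e for e in graph.edges if not e.directed]
    if undirected:
        raise ValueError(f"graph has undirected edges: {[e.key() for e in undirected]}")
    missing = [n for n in graph.nodes if n not in t_map]
    if missing:
        raise ValueError(f"pseudotimes missing for clusters {missing}")
    n = mat.n_cells
    cell_ll = assignment.cell_loglik
    src = np.full(n, -1, dtype=int)
    tgt = np.full(n, -1, dtype=int)
    pt = np.zeros(n)
    val = np.zeros(n)
    key = np.zeros(n)
    warned_isolated = set()
    for idx in range(n):
        k = int(assignment.labels[idx])
        incident = graph.incident(k)
        # incoming edges first: preferred on exact ties
        incident.sort(key=lambda e: (e.target != k, e.source, e.target))
        if not incident:
            if k not in warned_isolated:
                warnings.warn(f"cluster {k} is isolated; its cells keep t = t_k")
                warned_isolated.add(k)
            pt[idx] = t_map[k]
            val[idx] = cell_ll[idx, k - 1]
            continue
        best = None
        for e in incident:
            t, v = _edge_max(
                cell_ll[idx, e.source - 1],
                cell_ll[idx, e.target - 1],
                t_map[e.source],
                t_map[e.target],
                n_grid,
            )
            if best is None or v > best[0] + 0.0:
                best = (v, t, e)
        v, t, e = best
        src[idx], tgt[idx] = e.source, e.target
        pt[idx], val[idx] = t, v
        key[idx] = cell_ll[idx, e.target - 1] - cell_ll[idx, e.source - 1]
    return CellOrdering(
        cell_ids=list(mat.cell_ids),
        labels=assignment.labels.copy(),
        edge_source=src,
        edge_target=tgt,
        pseudotime=pt,
        interp_loglik=val,
        order_key=key,
        cluster_pseudotimes=dict(t_map),
        graph=graph,
    )


def order_path(ordering: CellOrdering, path: list[int]) -> pd.DataFrame:
    """Cells on a developmental path, sorted by pseudotime.

    ``path`` is an ordered cluster sequence whose consecutive pairs must
    all be directed edges of the graph (an anti-directional path is an
    error).  Cells assigned to those edges are sorted by (pseudotime,
    Λ_target − Λ_source ascending, cell id).
    """
    if len(path) < 2:
        raise ValueError("path needs at least two clusters")
    if ordering.graph is None:
        raise ValueError("ordering carries no graph")
    edge_keys = {(e.source, e.target) for e in ordering.graph.edges}
    pairs = list(zip(path[:-1], path[1:]))
    for p in pairs:
        if p not in edge_keys:
            raise ValueError(f"path edge {p[0]}→{p[1]} not in lineage graph")
    on_path = np.zeros(len(ordering.cell_ids), dtype=bool)
    for a, b in pairs:
        on_path |= (ordering.edge_source == a) & (ordering.edge_target == b)
    df = ordering.to_frame().loc[on_path].copy()
    df["order_key"] = ordering.order_key[on_path]
    df = df.sort_values(
        ["pseudotime", "order_key", "cell_id"], kind="stable"
    ).reset_index(drop=True)
    return df


def likelihood_landscape(
    mat: ExpressionMatrix,
    assignment: ClusterAssignment,
    embedding: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell negative log-likelihood under its own cluster.

    Higher values mark cells in broader, more uncertain expression states.
    Optional 2-D embedding coordinates are passed through for plotting.
    """
    n = mat.n_cells
    neg_ll = -assignment.cell_loglik[np.arange(n), assignment.labels - 1]
    out = pd.DataFrame(
        {"cell_id": mat.cell_ids, "cluster": assignment.labels, "neg_loglik": neg_ll}
    )
    if embedding is not None:
        embedding = np.asarray(embedding, dtype=float)
        if embedding.shape != (n, 2):
            raise ValueError("embedding must be (n_cells, 2)")
        out["dim1"] = embedding[:, 0]
        out["dim2"] = embedding[:, 1]
    return out
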