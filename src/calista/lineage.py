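"""Lineage-graph inference from cluster distances, and transition genes.

Cluster dissimilarity is likelihood-based: s_kj is the per-cell, per-gene
mean log-likelihood of cluster k's cells under cluster j's fitted
parameters; the normalized dissimilarity ŝ_kj = s_kk − s_kj is the drop in
likelihood from scoring cells under the wrong cluster, and the distance
d_kj = max(ŝ_kj, ŝ_jk) symmetrizes it.  Lineage graphs connect clusters
with small distances, either greedily (undirected) or using per-cell
capture times/stages (directed, with an outlier rule and feasible-parent
selection).  Transition genes along an edge are ranked by how much
likelihood is lost when the two clusters are merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .burst_model import ParamTable
from .clustering import ClusterAssignment, _fit_clusters, _gene_histograms
from .preprocess import ExpressionMatrix

__all__ = [
    "ClusterDistances",
    "LineageGraph",
    "TransitionGeneResult",
    "cluster_distances",
    "build_graph",
    "build_graph_timed",
    "direct_edges",
    "edit_graph",
    "start_cluster_from_markers",
    "transition_genes",
    "write_graphml",
]

logger = logging.getLogger(__name__)

#: normal-consistency constant for the scaled median absolute deviation
MAD_SCALE = 1.4826


@dataclass
class ClusterDistances:
    """Likelihood matrix S, normalized dissimilarities Ŝ, distances D."""

    S: np.ndarray  # (K, K): s_kj, per-cell per-gene mean log-likelihood
    S_hat: np.ndarray  # (K, K): s_kk − s_kj  (>= 0)
    D: np.ndarray  # (K, K): max(ŝ_kj, ŝ_jk), symmetric, zero diagonal

    @property
    def K(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    distance: float
    directed: bool = False

    def key(self) -> tuple[int, int]:
        """Canonical node pair (order-free for undirected edges)."""
        if self.directed:
            return (self.source, self.target)
        return (min(self.source, self.target), max(self.source, self.target))


@dataclass
class LineageGraph:
    """Cluster-level lineage graph (1-based cluster ids as nodes)."""

    nodes: list[int]
    edges: list[Edge] = field(default_factory=list)
    pseudotimes: dict[int, float] = field(default_factory=dict)
    stage_labels: dict[int, float] = field(default_factory=dict)

    def copy(self) -> "LineageGraph":
        return LineageGraph(
            nodes=list(self.nodes),
            edges=list(self.edges),
            pseudotimes=dict(self.pseudotimes),
            stage_labels=dict(self.stage_labels),
        )

    def has_edge(self, a: int, b: int) -> bool:
        return any(e.key() in ((a, b), (b, a)) for e in self.edges)

    def degree(self, node: int) -> int:
        return sum(1 for e in self.edges if node in (e.source, e.target))

    def incident(self, node: int) -> list[Edge]:
        return [e for e in self.edges if node in (e.source, e.target)]

    def to_networkx(self):
        import networkx as nx

        directed = any(e.directed for e in self.edges)
        g = nx.DiGraph() if directed else nx.Graph()
        for n in self.nodes:
            g.add_node(n, pseudotime=self.pseudotimes.get(n))
        for e in self.edges:
            g.add_edge(e.source, e.target, distance=e.distance, directed=e.directed)
        return g

    def to_edge_list(self) -> list[tuple[int, int, float, bool]]:
        return [(e.source, e.target, e.distance, e.directed) for e in self.edges]


def cluster_distances(
    assignment: ClusterAssignment,
    mat: ExpressionMatrix,
    table: ParamTable | None = None,
) -> ClusterDistances:
    """Likelihood-based K × K cluster dissimilarities and distances.

    s_kj = (1/|N_k|)(1/G) Σ_{n∈N_k} Σ_g ln P(m̂_{n,g}; θ*(g, j)); the same
    per-cell per-gene normalization is applied to the diagonal, so
    ŝ_kj = s_kk − s_kj is nonnegative and d_kj = max(ŝ_kj, ŝ_jk) is a
    symmetric distance with zero diagonal.
    """
    K, G = assignment.K, mat.n_genes
    cell_ll = assignment.cell_loglik  # (N, K), summed over genes
    S = np.zeros((K, K))
    for k in range(K):
        members = assignment.members(k + 1)
        if members.size < 2:
            warnings.warn(f"cluster {k + 1} has {members.size} cell(s); fits unstable")
        S[k, :] = cell_ll[members].mean(axis=0) / G
    S_hat = np.diag(S)[:, None] - S
    D = np.maximum(S_hat, S_hat.T)
    np.fill_diagonal(D, 0.0)
    return ClusterDistances(S=S, S_hat=S_hat, D=D)


def _sorted_candidate_edges(D: np.ndarray) -> list[tuple[float, int, int]]:
    """All node pairs ascending by (distance, source, target); 1-based ids."""
    K = D.shape[0]
    cands = [
        (float(D[i, j]), i + 1, j + 1) for i in range(K) for j in range(i + 1, K)
    ]
    return sorted(cands)


def build_graph(dist: ClusterDistances, ensure_connected: bool = True) -> LineageGraph:
    """Greedy undirected lineage graph from cluster distances.

    Adds edges in ascending distance (ties broken by the smaller node
    pair) until every cluster has degree >= 1; with ``ensure_connected``
    (default) continues until the graph is a single component.
    """
    K = dist.K
    if K < 2:
        raise ValueError("need at least two clusters")
    graph = LineageGraph(nodes=list(range(1, K + 1)))
    parent = list(range(K + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    degree = dict.fromkeys(graph.nodes, 0)
    for d, a, b in _sorted_candidate_edges(dist.D):
        if min(degree.values()) >= 1 and (
            not ensure_connected or len({find(n) for n in graph.nodes}) == 1
        ):
            break
        if graph.has_edge(a, b):
            continue
        graph.edges.append(Edge(a, b, d, directed=False))
        degree[a] += 1
        degree[b] += 1
        parent[find(a)] = find(b)
    return graph


def _mode(values: np.ndarray) -> float:
    """Most frequent value; ties resolve to the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])


def build_graph_timed(
    dist: ClusterDistances,
    assignment: ClusterAssignment,
    times: np.ndarray,
    time_percentile: float = 5.0,
    mad_factor: float = 3.0,
) -> LineageGraph:
    """Directed lineage graph using per-cell capture times/stages.

    Candidate edges whose distance exceeds median + ``mad_factor`` scaled
    MADs of the distance distribution are discarded as outliers.  Clusters
    are labeled by the mode of their members' times; the lowest-label
    cluster(s) are starts.  Every other cluster receives exactly one
    incoming edge from the nearest feasible parent — feasible parents have
    time labels nearest to, but not exceeding, the ``time_percentile``-th
    percentile of the cluster's member times — choosing the smallest
    cluster distance (ties to the smaller cluster id).
    """
    times = np.asarray(times, dtype=float)
    if times.shape[0] != assignment.labels.shape[0]:
        raise ValueError("times must be given for every cell")
    K = dist.K
    D = dist.D
    off = D[~np.eye(K, dtype=bool)]
    med = np.median(off)
    mad = MAD_SCALE * np.median(np.abs(off - med))
    cutoff_d = med + mad_factor * mad
    stage = {k: _mode(times[assignment.members(k)]) for k in range(1, K + 1)}
    start_label = min(stage.values())
    starts = [k for k, v in stage.items() if v == start_label]
    graph = LineageGraph(nodes=list(range(1, K + 1)), stage_labels=stage)
    order = sorted((stage[k], k) for k in graph.nodes)
    for _, k in order:
        if k in starts:
            continue
        t_cut = np.percentile(times[assignment.members(k)], time_percentile)
        cand_labels = [stage[c] for c in graph.nodes if c != k and stage[c] <= t_cut]
        if not cand_labels:
            raise ValueError(
                f"no feasible parent for cluster {k} "
                f"(time cutoff {t_cut:.3g}); add an edge manually with edit_graph"
            )
        nearest = max(cand_labels)
        feasible = [c for c in graph.nodes if c != k and stage[c] == nearest]
        feasible = [c for c in feasible if D[c - 1, k - 1] <= cutoff_d]
        if not feasible:
            raise ValueError(
                f"all candidate parents of cluster {k} are distance outliers; "
                "add an edge manually with edit_graph"
            )
        parent = min(feasible, key=lambda c: (D[c - 1, k - 1], c))
        graph.edges.append(Edge(parent, k, float(D[parent - 1, k - 1]), directed=True))
    return graph


def start_cluster_from_markers(
    assignment: ClusterAssignment,
    mat: ExpressionMatrix,
    marker_genes: list[str],
    highest: bool = True,
) -> int:
    """Pick the start cluster from expected marker expression.

    Returns the cluster whose mean expression over ``marker_genes`` is
    highest (``highest=True``, e.g. pluripotency markers) or lowest
    (``highest=False``, markers of the terminal fate).
    """
    idx = [mat.gene_names.index(g) for g in marker_genes]
    means = np.array(
        [mat.values[assignment.members(k)][:, idx].mean() for k in range(1, assignment.K + 1)]
    )
    return int(np.argmax(means) + 1) if highest else int(np.argmin(means) + 1)


def write_graphml(graph: LineageGraph, path) -> None:
    """Export the lineage graph as GraphML (via networkx)."""
    import networkx as nx

    g = graph.to_networkx()
    for n, data in g.nodes(data=True):
        if data.get("pseudotime") is None:
            data.pop("pseudotime", None)
    nx.write_graphml(g, path)


def direct_edges(graph: LineageGraph, cluster_pseudotimes: dict[int, float]) -> LineageGraph:
    """Orient every edge from lower to higher cluster pseudotime.

    Equal-pseudotime edges are left undirected with a warning.  Idempotent
    on already-directed graphs.
    """
    missing = [n for n in graph.nodes if n not in cluster_pseudotimes]
    if missing:
        raise ValueError(f"pseudotimes missing for clusters {missing}")
    out = graph.copy()
    out.pseudotimes = dict(cluster_pseudotimes)
    new_edges = []
    for e in out.edges:
        ts, tt = cluster_pseudotimes[e.source], cluster_pseudotimes[e.target]
        if ts == tt:
            if not e.directed:
                warnings.warn(
                    f"edge {e.source}-{e.target} has equal pseudotimes; left undirected"
                )
            new_edges.append(replace(e, directed=e.directed))
        elif ts < tt:
            new_edges.append(replace(e, directed=True))
        else:
            new_edges.append(Edge(e.target, e.source, e.distance, directed=True))
    out.edges = new_edges
    return out


def edit_graph(
    graph: LineageGraph,
    add: list[tuple[int, int]] = (),
    remove: list[tuple[int, int]] = (),
) -> LineageGraph:
    """Programmatic manual curation: add and remove edges.

    Each edit is logged.  Adding an existing edge or removing a missing
    one is an error; removing an edge that isolates a node is allowed with
    a warning.
    """
    out = graph.copy()
    for a, b in add:
        if a not in out.nodes or b not in out.nodes:
            raise ValueError(f"edge ({a}, {b}) references unknown node")
        if out.has_edge(a, b):
            raise ValueError(f"edge ({a}, {b}) already present")
        out.edges.append(Edge(a, b, np.nan, directed=False))
        logger.info("edit_graph: added edge %s-%s", a, b)
    for a, b in remove:
        match = [e for e in out.edges if e.key() in ((a, b), (b, a))]
        if not match:
            raise ValueError(f"edge ({a}, {b}) not in graph")
        out.edges.remove(match[0])
        logger.info("edit_graph: removed edge %s-%s", a, b)
        for n in (a, b):
            if out.degree(n) == 0:
                warnings.warn(f"removing edge ({a}, {b}) isolated node {n}")
    return out


@dataclass
class TransitionGeneResult:
    """Per-gene transition scores for one lineage edge.

    ``score[g] = v_g^j + v_g^k − v_g^{j+k}`` is the log-likelihood gained
    by fitting the two clusters separately rather than pooled; it is
    nonnegative.  ``order`` ranks genes by decreasing score; ``selected``
    is the shortest prefix of the ranking whose scores sum to at least
    ``threshold`` of the total.
    """

    edge: tuple[int, int]
    score: np.ndarray  # (G,) v_g^jk in original gene order
    v_j: np.ndarray
    v_k: np.ndarray
    v_pooled: np.ndarray
    order: np.ndarray  # gene indices, decreasing score
    selected: np.ndarray  # gene indices (prefix of order)
    threshold: float
    tie_rel: float = 0.8
    gene_names: list[str] = field(default_factory=list)


def transition_genes(
    assignment: ClusterAssignment,
    mat: ExpressionMatrix,
    table: ParamTable,
    edge: tuple[int, int],
    threshold: float = 0.5,
    tie_rel: float = 0.8,
) -> TransitionGeneResult:
    """Rank genes by the likelihood cost of merging two connected clusters.

    The selected set is the shortest prefix of the decreasing ranking whose
    scores sum to at least ``threshold`` of the total, extended while the
    next gene's score stays within ``tie_rel`` of the last included one —
    genes carrying statistically indistinguishable information are kept or
    dropped together rather than split by an arbitrary cumulative cutoff.
    """
    j, k = edge
    for c in (j, k):
        if c < 1 or c > assignment.K:
            raise ValueError(f"cluster {c} not in assignment (K={assignment.K})")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    counts = mat.counts()
    mj, mk = assignment.members(j), assignment.members(k)
    v_j = assignment.cluster_gene_loglik[j - 1]
    v_k = assignment.cluster_gene_loglik[k - 1]
    hist = _gene_histograms(counts[np.concatenate([mj, mk])], table.m_cap)
    v_pooled = table.loglik_from_histogram(hist).max(axis=0)
    score = np.maximum(v_j + v_k - v_pooled, 0.0)
    order = np.lexsort((np.arange(score.size), -score))
    total = score.sum()
    if total == 0:
        warnings.warn(f"all transition-gene scores zero on edge {edge}")
        selected = np.array([], dtype=int)
    else:
        csum = np.cumsum(score[order])
        n_sel = int(np.searchsorted(csum, threshold * total) + 1)
        while (
            n_sel < score.size
            and score[order[n_sel]] > 0
            and score[order[n_sel]] >= tie_rel * score[order[n_sel - 1]]
        ):
            n_sel += 1
        selected = order[:n_sel]
    return TransitionGeneResult(
        edge=(j, k),
        score=score,
        v_j=v_j,
        v_k=v_k,
        v_pooled=v_pooled,
        order=order,
        selected=selected,
        threshold=threshold,
        tie_rel=tie_rel,
        gene_names=list(mat.gene_names),
    )
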