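"""Model-based single-cell clustering.

Cells are grouped by maximizing the joint telegraph-model likelihood of
their (scaled) counts: a greedy algorithm alternates per-(cluster, gene)
grid fits with reassignment of each cell to its maximum-likelihood
cluster.  Many greedy runs from random starts are aggregated into a
consensus co-assignment matrix, finalized with PAM k-medoids; the number
of clusters can be chosen by the eigengap of the consensus Laplacian.  A
large-data mode skips the consensus and keeps the best single run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .burst_model import ParamTable, TwoStateParams
from .preprocess import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "ConsensusMatrix",
    "greedy_cluster",
    "run_consensus",
    "finalize_kmedoids",
    "select_n_clusters",
    "cluster_large",
    "assignment_from_labels",
]


@dataclass
class ClusterAssignment:
    """Result of a likelihood-based clustering.

    ``labels`` are 1-based cluster ids; ``param_idx[k, g]`` indexes the
    table grid point fitted to gene ``g`` of cluster ``k+1``;
    ``cell_loglik[n, k]`` is Λ_{k+1}(n), the log-likelihood of cell ``n``
    under cluster ``k+1``'s fitted parameters summed over genes.
    """

    labels: np.ndarray  # (N,) ints in 1..K
    K: int
    param_idx: np.ndarray  # (K, G) table grid indices
    cluster_gene_loglik: np.ndarray  # (K, G) Σ_{n∈N_k} ln P at the fitted point
    cell_loglik: np.ndarray  # (N, K)
    total_loglik: float
    table: ParamTable
    converged: bool = True
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default=None)

    def params(self, k: int, g: int) -> TwoStateParams:
        """Fitted parameters of gene ``g`` (0-based) in cluster ``k`` (1-based)."""
        return self.table.params_at(int(self.param_idx[k - 1, g]))

    def members(self, k: int) -> np.ndarray:
        """Cell indices of cluster ``k`` (1-based)."""
        return np.where(self.labels == k)[0]


@dataclass
class ConsensusMatrix:
    """Co-assignment counts over repeated greedy runs."""

    counts: np.ndarray  # (N, N) symmetric ints
    n_runs: int

    def distances(self) -> np.ndarray:
        """Consensus dissimilarity d(i, j) = n_runs − counts(i, j)."""
        return (self.n_runs - self.counts).astype(float)

    def similarity(self) -> np.ndarray:
        return self.counts / self.n_runs


def _gene_histograms(counts: np.ndarray, m_cap: int) -> np.ndarray:
    """(m_cap+1, G) per-gene count histograms."""
    n, g = counts.shape
    # bincount on a flattened (gene-offset) array: one pass for all genes
    flat = counts + np.arange(g) * (m_cap + 1)
    hist = np.bincount(flat.ravel(), minlength=g * (m_cap + 1))
    return hist.reshape(g, m_cap + 1).T.astype(float)


def _fit_clusters(
    counts: np.ndarray, labels: np.ndarray, K: int, table: ParamTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(cluster, gene) grid argmax. Returns (param_idx, gene_loglik)."""
    g = counts.shape[1]
    param_idx = np.zeros((K, g), dtype=np.int64)
    gene_ll = np.zeros((K, g))
    for k in range(K):
        members = labels == k + 1
        if not members.any():
            continue
        hist = _gene_histograms(counts[members], table.m_cap)
        ll = table.loglik_from_histogram(hist)  # (P, G)
        param_idx[k] = np.argmax(ll, axis=0)
        gene_ll[k] = ll[param_idx[k], np.arange(g)]
    return param_idx, gene_ll


def _cell_logliks(
    counts: np.ndarray, param_idx: np.ndarray, table: ParamTable
) -> np.ndarray:
    """Λ_k(n) for every cell and cluster: (N, K)."""
    k_, g = param_idx.shape
    out = np.empty((counts.shape[0], k_))
    for k in range(k_):
        out[:, k] = table.log_pmf[param_idx[k][None, :], counts].sum(axis=1)
    return out


def greedy_cluster(
    mat: ExpressionMatrix,
    K: int,
    table: ParamTable,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Greedy maximum-likelihood clustering from a random start.

    Alternates (a) exact per-(cluster, gene) grid fits and (b) reassignment
    of every cell to its argmax-likelihood cluster (ties to the lowest
    cluster index) until labels are stable or ``max_iter`` is reached.  The
    total log-likelihood is non-decreasing across iterations.  A cluster
    emptied by reassignment is repaired by moving in the globally
    worst-fitting cell.
    """
    counts = mat.counts()
    n = counts.shape[0]
    if not (2 <= K <= n) and K != 1:
        raise ValueError(f"K={K} outside [1, {n}]")
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, K + 1, size=n)
    trace = []
    converged = False
    it = 0
    param_idx = gene_ll = cell_ll = None
    for it in range(1, max_iter + 1):
        param_idx, gene_ll = _fit_clusters(counts, labels, K, table)
        cell_ll = _cell_logliks(counts, param_idx, table)
        new_labels = np.argmax(cell_ll, axis=1) + 1  # first max -> lowest index
        trace.append(float(cell_ll[np.arange(n), new_labels - 1].sum()))
        # empty-cluster repair: donate the globally worst-fitting cell
        for k in range(1, K + 1):
            if not np.any(new_labels == k):
                fit = cell_ll[np.arange(n), new_labels - 1].copy()
                sizes = np.bincount(new_labels, minlength=K + 1)
                fit[sizes[new_labels] <= 1] = np.inf  # don't empty another cluster
                new_labels[int(np.argmin(fit))] = k
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    if not converged:
        warnings.warn(f"greedy clustering did not converge in {max_iter} iterations")
    param_idx, gene_ll = _fit_clusters(counts, labels, K, table)
    cell_ll = _cell_logliks(counts, param_idx, table)
    total = float(cell_ll[np.arange(n), labels - 1].sum())
    return ClusterAssignment(
        labels=labels,
        K=K,
        param_idx=param_idx,
        cluster_gene_loglik=gene_ll,
        cell_loglik=cell_ll,
        total_loglik=total,
        table=table,
        converged=converged,
        n_iter=it,
        loglik_trace=np.array(trace),
    )


def assignment_from_labels(
    mat: ExpressionMatrix, labels: np.ndarray, table: ParamTable
) -> ClusterAssignment:
    """Fit cluster parameters for an externally provided labeling (1..K)."""
    counts = mat.counts()
    labels = np.asarray(labels, dtype=np.int64)
    K = int(labels.max())
    if np.any(labels < 1):
        raise ValueError("labels must be 1-based")
    param_idx, gene_ll = _fit_clusters(counts, labels, K, table)
    cell_ll = _cell_logliks(counts, param_idx, table)
    total = float(cell_ll[np.arange(counts.shape[0]), labels - 1].sum())
    return ClusterAssignment(
        labels=labels,
        K=K,
        param_idx=param_idx,
        cluster_gene_loglik=gene_ll,
        cell_loglik=cell_ll,
        total_loglik=total,
        table=table,
    )


def _greedy_runs(mat, K, table, n_runs, base_seed, max_iter, workers):
    if workers and workers > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=workers)(
            delayed(greedy_cluster)(mat, K, table, seed=base_seed + i, max_iter=max_iter)
            for i in range(n_runs)
        )
    return [
        greedy_cluster(mat, K, table, seed=base_seed + i, max_iter=max_iter)
        for i in range(n_runs)
    ]


def run_consensus(
    mat: ExpressionMatrix,
    K: int,
    table: ParamTable,
    n_runs: int = 50,
    base_seed: int = 0,
    workers: int = 1,
    max_iter: int = 100,
) -> ConsensusMatrix:
    """Aggregate co-assignment counts over independent greedy runs.

    Run ``i`` always uses seed ``base_seed + i``, so the result is
    identical for any ``workers`` count or scheduling.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    n = mat.n_cells
    counts = np.zeros((n, n), dtype=np.int64)
    for res in _greedy_runs(mat, K, table, n_runs, base_seed, max_iter, workers):
        same = res.labels[:, None] == res.labels[None, :]
        counts += same
    return ConsensusMatrix(counts=counts, n_runs=n_runs)


def _pam_assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    assign = np.argmin(sub, axis=1)
    return assign, float(sub[np.arange(D.shape[0]), assign].sum())


def finalize_kmedoids(
    cons: ConsensusMatrix, K: int, seed: int = 0, max_swaps: int = 300
) -> np.ndarray:
    """PAM k-medoids on the consensus dissimilarity; returns 1-based labels.

    Deterministic greedy BUILD initialization followed by best-improvement
    SWAP (at most ``max_swaps`` swaps); ties resolve to the lowest index.
    The ``seed`` is accepted for interface uniformity but the procedure is
    fully deterministic.
    """
    D = cons.distances()
    n = D.shape[0]
    if K > n:
        raise ValueError(f"K={K} > {n} cells")
    if np.all(D[~np.eye(n, dtype=bool)] == D[0, 1] if n > 1 else True):
        warnings.warn("all consensus distances equal; split is arbitrary but deterministic")
    # BUILD: start from the 1-medoid optimum, then greedily add
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < K:
        cur = D[:, medoids].min(axis=1)
        # gain of adding candidate c = sum of improvements
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    assign, cost = _pam_assign(D, medoids)
    for _ in range(max_swaps):
        best = (0.0, None, None)
        non_med = np.setdiff1d(np.arange(n), medoids)
        for mi in range(K):
            trial = medoids.copy()
            for c in non_med:
                trial[mi] = c
                _, tc = _pam_assign(D, trial)
                if cost - tc > best[0] + 1e-12:
                    best = (cost - tc, mi, c)
            trial[mi] = medoids[mi]
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)
        assign, cost = _pam_assign(D, medoids)
    return assign + 1


def select_n_clusters(
    mat: ExpressionMatrix,
    table: ParamTable,
    K_range: list[int],
    n_runs: int = 50,
    seed: int = 0,
    workers: int = 1,
) -> tuple[int, dict[int, float], np.ndarray]:
    """Choose the cluster number by the consensus-Laplacian eigengap.

    Builds a consensus at max(K_range), forms the normalized graph
    Laplacian of the consensus similarity, and returns the K in ``K_range``
    maximizing the eigengap λ_{K+1} − λ_K, together with the per-K gaps and
    the eigenvalue spectrum.  When no candidate gap stands out against the
    leading (K = 1) spectral gap — the signature of a single homogeneous
    population — the smallest K is returned with a warning.
    """
    K_range = sorted(set(int(k) for k in K_range))
    if len(K_range) < 2:
        raise ValueError("K_range must contain at least two values")
    cons = run_consensus(mat, max(K_range), table, n_runs=n_runs, base_seed=seed, workers=workers)
    S = cons.similarity()
    deg = S.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    L = np.eye(S.shape[0]) - dinv[:, None] * S * dinv[None, :]
    evals = np.linalg.eigvalsh(L)
    gaps = {k: float(evals[k] - evals[k - 1]) for k in K_range if k < evals.size}
    trivial_gap = float(evals[1] - evals[0]) if evals.size > 1 else 0.0
    if not gaps or max(gaps.values()) < max(1e-12, 0.3 * trivial_gap):
        warnings.warn("no prominent eigengap in K_range; defaulting to smallest K")
        return K_range[0], gaps, evals
    chosen = max(gaps, key=lambda k: (gaps[k], -k))
    return chosen, gaps, evals


def cluster_large(
    mat: ExpressionMatrix,
    K: int,
    table: ParamTable,
    n_runs: int = 10,
    seed: int = 0,
    workers: int = 1,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Consensus bypass for large data: best-likelihood greedy run.

    Runs the greedy algorithm ``n_runs`` times and keeps the clustering
    with the highest total log-likelihood (ties to the lowest seed).
    """
    runs = _greedy_runs(mat, K, table, n_runs, seed, max_iter, workers)
    best = max(range(len(runs)), key=lambda i: (runs[i].total_loglik, -i))
    return runs[best]
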