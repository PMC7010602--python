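"""Expression-matrix preprocessing.

Turns raw expression matrices (RT-qPCR 2^−ΔCt values, plate-based log
RPKM/TPM, or droplet UMI counts) into the scaled integer matrix the
telegraph-model likelihoods consume: median-based UMI normalization,
zero-fraction filtering, informative-gene selection, log-stretch scaling to
the 0–200 count range, dropout-rate estimation, and likelihood-based gene
ranking with an elbow cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .burst_model import DropoutModel, NO_DROPOUT, ParamTable

__all__ = [
    "ExpressionMatrix",
    "GeneRanking",
    "normalize_umi",
    "filter_zero_fraction",
    "select_informative_genes",
    "scale_expression",
    "estimate_dropout_lambda",
    "rank_genes_by_likelihood",
]

SCALE_MAX = 200

DATA_KINDS = ("qpcr", "rnaseq_log", "umi")


@dataclass
class ExpressionMatrix:
    """Cells × genes expression matrix with labels and metadata.

    ``values[n, g]`` is the expression of gene ``g`` in cell ``n``.  After
    :func:`scale_expression` the values are integers in [0, 200] and the
    ``scaled`` flag is set.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_names: list[str]
    capture_times: np.ndarray | None = None
    data_kind: str = "rnaseq_log"
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        n, g = self.values.shape
        self.cell_ids = list(self.cell_ids)
        self.gene_names = list(self.gene_names)
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.capture_times is not None:
            self.capture_times = np.asarray(self.capture_times, dtype=float)
            if self.capture_times.shape != (n,):
                raise ValueError("capture_times length must equal number of cells")
        if self.data_kind not in DATA_KINDS:
            raise ValueError(f"data_kind must be one of {DATA_KINDS}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def counts(self) -> np.ndarray:
        """Integer count matrix (requires the scaled flag)."""
        if not self.scaled:
            raise ValueError("matrix is not scaled; call scale_expression first")
        return self.values.astype(np.int64)

    def subset(self, cells=None, genes=None) -> "ExpressionMatrix":
        """New matrix restricted to the given cell / gene index arrays."""
        cells = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        genes = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        return ExpressionMatrix(
            values=self.values[np.ix_(cells, genes)],
            cell_ids=[self.cell_ids[i] for i in cells],
            gene_names=[self.gene_names[j] for j in genes],
            capture_times=None if self.capture_times is None else self.capture_times[cells],
            data_kind=self.data_kind,
            scaled=self.scaled,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            gene_names=list(self.gene_names),
            capture_times=None if self.capture_times is None else self.capture_times.copy(),
            data_kind=self.data_kind,
            scaled=self.scaled,
        )


def normalize_umi(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-totals UMI normalization.

    Each count is divided by its cell's total UMI count and multiplied by
    the median of the per-cell totals, so every cell ends up with the same
    total while within-cell proportions are conserved.
    """
    if mat.data_kind != "umi":
        raise ValueError(f"normalize_umi expects UMI data, got {mat.data_kind}")
    totals = mat.values.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        ids = [mat.cell_ids[i] for i in zero]
        raise ValueError(f"cells with zero total UMI count: {ids}")
    out = mat.copy()
    out.values = mat.values / totals[:, None] * np.median(totals)
    return out


def filter_zero_fraction(
    mat: ExpressionMatrix,
    gene_thresh: float = 1.0,
    cell_thresh: float = 1.0,
) -> ExpressionMatrix:
    """Remove high-zero genes, then high-zero cells.

    A gene (cell) is removed when its fraction of zero entries reaches the
    threshold; the defaults (1.0 / 1.0) remove only all-zero columns and
    rows.  Genes are filtered before cells, in a single pass.
    """
    for name, t in (("gene_thresh", gene_thresh), ("cell_thresh", cell_thresh)):
        if not (0 < t <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {t}")
    gene_zero = (mat.values == 0).mean(axis=0)
    keep_genes = np.where(gene_zero < gene_thresh)[0]
    if keep_genes.size == 0:
        raise ValueError("all genes removed by zero-fraction filter")
    sub = mat.subset(genes=keep_genes)
    cell_zero = (sub.values == 0).mean(axis=1)
    keep_cells = np.where(cell_zero < cell_thresh)[0]
    if keep_cells.size == 0:
        raise ValueError("all cells removed by zero-fraction filter")
    return sub.subset(cells=keep_cells)


def _dispersion_zscores(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Within-bin standardized dispersion (variance/mean), binned by mean.

    Genes are placed into ``n_bins`` equal-count bins of mean expression and
    the Fano-style dispersion is z-scored within each bin, removing the
    mean–dispersion trend before ranking.
    """
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    g = mean.size
    n_bins = min(n_bins, g)
    z = np.zeros(g)
    for edges in np.array_split(order, n_bins):
        d = disp[edges]
        sd = d.std()
        z[edges] = (d - d.mean()) / sd if sd > 0 else 0.0
    return z


def select_informative_genes(
    mat: ExpressionMatrix, pct_of_cells: float = 0.5
) -> ExpressionMatrix:
    """Keep the Y = min(200, G, ⌊pct · N⌋) most dispersed genes.

    Ranking uses the within-bin standardized dispersion; ties resolve to
    the lower gene index.
    """
    if mat.data_kind not in ("rnaseq_log", "umi"):
        raise ValueError("informative-gene selection applies to scRNA-seq data")
    if not (0 < pct_of_cells <= 1):
        raise ValueError("pct_of_cells must be in (0, 1]")
    y = min(SCALE_MAX, mat.n_genes, int(np.floor(pct_of_cells * mat.n_cells)))
    if y < 2:
        raise ValueError(f"informative-gene count Y={y} < 2")
    if y == mat.n_genes:
        return mat.copy()
    z = _dispersion_zscores(mat.values)
    # stable sort on -z keeps lower index first among ties
    top = np.sort(np.argsort(-z, kind="stable")[:y])
    return mat.subset(genes=top)


def scale_expression(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Log-stretch each gene onto the integer range [0, 200].

    Applies the monotone per-gene transform
    ``m̂ = 2^(log2(m+1) · log2(201) / log2(m_max+1)) − 1`` followed by
    rounding, so zero maps to zero and the gene maximum maps to exactly
    200.  Sets the ``scaled`` flag; re-application is rejected.
    """
    if mat.scaled:
        raise ValueError("matrix already scaled")
    m_max = mat.values.max(axis=0)
    bad = np.where(m_max == 0)[0]
    if bad.size:
        names = [mat.gene_names[j] for j in bad]
        raise ValueError(f"genes with zero maximum (filter first): {names}")
    expo = np.log2(mat.values + 1.0) * (np.log2(SCALE_MAX + 1.0) / np.log2(m_max + 1.0))
    out = mat.copy()
    out.values = np.rint(np.exp2(expo) - 1.0)
    out.scaled = True
    return out


def estimate_dropout_lambda(mat: ExpressionMatrix) -> DropoutModel:
    """Estimate the dropout decay constant λ from zero fractions.

    Fits zero-fraction_g ≈ e^(−λ · mean_g) across genes by ordinary least
    squares of ln(zero fraction) on mean expression through the origin,
    using genes with zero fraction strictly inside (0, 1).  A matrix with
    no zeros returns the no-dropout sentinel (λ = inf).
    """
    if mat.n_genes < 10:
        raise ValueError("need >= 10 genes to estimate dropout")
    zf = (mat.values == 0).mean(axis=0)
    mean = mat.values.mean(axis=0)
    if np.all(zf == 0):
        return NO_DROPOUT
    use = (zf > 0) & (zf < 1) & (mean > 0)
    if use.sum() >= 2:
        lam = -np.sum(mean[use] * np.log(zf[use])) / np.sum(mean[use] ** 2)
    else:
        warnings.warn("degenerate dropout fit; falling back to two-point estimate")
        cand = np.where((zf > 0) & (zf < 1) & (mean > 0))[0]
        if cand.size == 0:
            return NO_DROPOUT
        j = cand[np.argmax(mean[cand])]
        lam = -np.log(zf[j]) / mean[j]
    return DropoutModel(max(0.0, float(lam)))


@dataclass
class GeneRanking:
    """Genes ordered by increasing gene-wise maximum log-likelihood.

    Lower likelihood means a broader expression distribution (more
    informative gene); genes past the elbow cutoff are flagged for removal.
    """

    order: np.ndarray  # gene indices, increasing likelihood
    loglik: np.ndarray  # v^g aligned with order
    cutoff: int  # elbow position within the ordered list
    gene_names: list[str] = field(default_factory=list)

    @property
    def keep_indices(self) -> np.ndarray:
        """Original gene indices retained (at or below the elbow)."""
        return np.sort(self.order[: self.cutoff + 1])


def _elbow_index(y: np.ndarray) -> int:
    """Index of maximum perpendicular distance to the endpoint chord."""
    n = y.size
    if n < 3:
        return n - 1
    x = np.arange(n, dtype=float)
    p0 = np.array([0.0, y[0]])
    p1 = np.array([n - 1.0, y[-1]])
    d = p1 - p0
    norm = np.hypot(*d)
    if norm == 0:
        return n - 1
    # cross-product distance of each point to the chord
    dist = np.abs(d[0] * (y - p0[1]) - d[1] * (x - p0[0])) / norm
    return int(np.argmax(dist))


def rank_genes_by_likelihood(mat: ExpressionMatrix, table: ParamTable) -> GeneRanking:
    """Rank genes by their gene-wise maximum log-likelihood, with elbow cutoff.

    Treats all cells as a single cluster: v^g = max_θ Σ_n ln P(m̂_{n,g}; θ)
    over the table grid.  Genes are sorted in increasing v^g (broad,
    informative genes first); genes above the elbow of the (rank, v^g)
    curve are flagged for removal.  UMI data requires a dropout-aware table.
    """
    counts = mat.counts()
    if mat.data_kind == "umi" and table.dropout is None:
        raise ValueError("UMI data requires a dropout-aware parameter table")
    hist = np.stack(
        [np.bincount(counts[:, g], minlength=table.m_cap + 1) for g in range(mat.n_genes)],
        axis=1,
    ).astype(float)
    v = table.loglik_from_histogram(hist).max(axis=0)  # (G,)
    order = np.lexsort((np.arange(v.size), v))
    cutoff = _elbow_index(v[order])
    return GeneRanking(
        order=order,
        loglik=v[order],
        cutoff=cutoff,
        gene_names=[mat.gene_names[j] for j in order],
    )
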