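"""File formats, run configuration, manifest, and pipeline orchestration.

Dense matrices are CSV/TSV with a header row of gene names and a first
column of cell ids; sparse matrices follow the 10x MatrixMarket
convention (genes × cells ``matrix.mtx`` plus ``barcodes.tsv`` and
``features.tsv``, transposed to cells × genes on load).  Capture times
come from a two-column TSV (cell_id, time).  All user-facing cluster ids
are 1-based.  ``run_pipeline`` chains the stages with shared seeds and
records a JSON manifest of inputs, configuration and outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burst_model import DropoutModel, ParamTable, build_param_table
from .preprocess import (
    ExpressionMatrix,
    estimate_dropout_lambda,
    filter_zero_fraction,
    normalize_umi,
    scale_expression,
    select_informative_genes,
)

__all__ = [
    "RunConfig",
    "read_matrix",
    "read_capture_times",
    "write_matrix_csv",
    "write_outputs",
    "run_pipeline",
    "load_or_build_table",
]


def read_matrix(
    path,
    format: str = "csv",
    data_kind: str = "rnaseq_log",
    times_path=None,
) -> ExpressionMatrix:
    """Load an expression matrix as cells × genes.

    ``format='csv'``/``'tsv'``: dense, cells in rows, gene-name header,
    first column of cell ids.  ``format='mtx'``: path is the ``.mtx`` file
    of a 10x-style triplet (genes × cells; transposed on load) with
    ``barcodes.tsv`` / ``features.tsv`` alongside.
    """
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        cell_ids = [str(c) for c in df.index]
        gene_names = [str(g) for g in df.columns]
    elif format == "mtx":
        from scipy.io import mmread

        m = mmread(path).toarray()  # genes x cells on disk
        barcodes = _read_single_column(path.parent / "barcodes.tsv")
        features = _read_single_column(path.parent / "features.tsv")
        if m.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"matrix is {m.shape} but {len(features)} features x {len(barcodes)} barcodes"
            )
        values = m.T.astype(float)
        cell_ids, gene_names = barcodes, features
    else:
        raise ValueError(f"unknown format {format!r}")
    if np.any(~np.isfinite(values)):
        raise ValueError("matrix contains NaN or infinite entries")
    times = None
    if times_path is not None:
        times = read_capture_times(times_path, cell_ids)
    return ExpressionMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_names=gene_names,
        capture_times=times,
        data_kind=data_kind,
    )


def _read_single_column(path) -> list[str]:
    with open(path) as f:
        return [line.split("\t")[0].strip() for line in f if line.strip()]


def read_capture_times(path, cell_ids: list[str]) -> np.ndarray:
    """Two-column TSV (cell_id, time) aligned to the matrix's cell order."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "time"])
    lookup = dict(zip(df["cell_id"].astype(str), df["time"].astype(float)))
    missing = [c for c in cell_ids if c not in lookup]
    if missing:
        raise ValueError(f"{len(missing)} cells missing capture times, e.g. {missing[:3]}")
    return np.array([lookup[c] for c in cell_ids])


def write_matrix_csv(mat: ExpressionMatrix, path) -> None:
    pd.DataFrame(mat.values, index=mat.cell_ids, columns=mat.gene_names).to_csv(path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(results: dict, out_dir, config: dict | None = None) -> dict:
    """Write stage outputs and a JSON manifest.

    ``results`` maps stage name → dict of {filename: writer(path)} or
    None for an absent stage.  The manifest records the package version,
    config, per-file content hashes and timestamps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "calista-sc",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config or {},
        "stages": {},
    }
    for stage, files in results.items():
        if files is None:
            manifest["stages"][stage] = {"present": False}
            continue
        entry = {"present": True, "files": {}}
        for fname, writer in files.items():
            fpath = out_dir / fname
            writer(fpath)
            entry["files"][fname] = _sha256(fpath)
        manifest["stages"][stage] = entry
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (all thresholds documented)."""

    input_path: str | None = None
    input_format: str = "csv"
    data_kind: str = "rnaseq_log"
    times_path: str | None = None
    gene_zero_thresh: float = 1.0
    cell_zero_thresh: float = 1.0
    pct_of_cells: float = 0.5
    dropout: str | float = "none"  # "auto", "none", or a numeric lambda
    K: int | None = None
    K_range: tuple[int, int] = (2, 8)
    n_runs: int = 50
    large_mode: bool = False
    transition_threshold: float = 0.5
    window_fraction: float = 0.1
    r_min: float = 0.8
    p_max: float = 0.01
    seed: int = 0
    workers: int = 1
    out_dir: str = "calista_out"
    table_cache: str | None = None

    def validate(self) -> None:
        for name, v, lo, hi in (
            ("gene_zero_thresh", self.gene_zero_thresh, 0, 1),
            ("cell_zero_thresh", self.cell_zero_thresh, 0, 1),
            ("pct_of_cells", self.pct_of_cells, 0, 1),
            ("transition_threshold", self.transition_threshold, 0, 1),
            ("r_min", self.r_min, 0, 1),
            ("p_max", self.p_max, 0, 1),
        ):
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")


def load_or_build_table(
    dropout: DropoutModel | None = None, cache_path=None
) -> ParamTable:
    """Default-grid table, optionally persisted to an HDF5 cache file."""
    if cache_path is not None and Path(cache_path).exists():
        table = ParamTable.load(cache_path)
        want_lam = None if dropout is None else float(dropout.lam)
        have_lam = None if table.dropout is None else float(table.dropout.lam)
        if want_lam == have_lam:
            return table
        warnings.warn("table cache has a different dropout model; rebuilding")
    table = build_param_table(dropout=dropout)
    if cache_path is not None:
        table.save(cache_path)
    return table


def preprocess_stage(mat: ExpressionMatrix, config: RunConfig) -> tuple[ExpressionMatrix, DropoutModel | None]:
    """Normalization, filtering, gene selection, dropout fit, scaling."""
    if mat.data_kind == "umi":
        mat = normalize_umi(mat)
    mat = filter_zero_fraction(mat, config.gene_zero_thresh, config.cell_zero_thresh)
    if mat.data_kind in ("rnaseq_log", "umi"):
        mat = select_informative_genes(mat, config.pct_of_cells)
    dropout = None
    if config.dropout == "auto":
        dropout = estimate_dropout_lambda(mat)
    elif config.dropout not in ("none", None):
        dropout = DropoutModel(float(config.dropout))
    mat = scale_expression(mat)
    return mat, dropout


def run_pipeline(config: RunConfig, mat: ExpressionMatrix | None = None) -> dict:
    """Execute preprocess → cluster → lineage → genes → order.

    Pass ``mat`` directly or set ``config.input_path``.  Results are
    written under ``config.out_dir`` together with a manifest; the dict of
    in-memory stage results is returned.
    """
    from .clustering import cluster_large, finalize_kmedoids, run_consensus, select_n_clusters
    from .clustering import assignment_from_labels
    from .lineage import build_graph, build_graph_timed, cluster_distances, direct_edges, transition_genes
    from .pseudotime import (
        assign_cells_to_edges,
        cluster_pseudotimes_from_distances,
        cluster_pseudotimes_from_times,
    )

    config.validate()
    if mat is None:
        if config.input_path is None:
            raise ValueError("either mat or config.input_path is required")
        mat = read_matrix(
            config.input_path, config.input_format, config.data_kind, config.times_path
        )
    mat, dropout = preprocess_stage(mat, config)
    no_dropout = dropout is None or dropout.is_no_dropout
    table = load_or_build_table(None if no_dropout else dropout, config.table_cache)

    if config.K is None:
        K, _, _ = select_n_clusters(
            mat, table, list(range(config.K_range[0], config.K_range[1] + 1)),
            n_runs=config.n_runs, seed=config.seed, workers=config.workers,
        )
    else:
        K = config.K
    if config.large_mode:
        assignment = cluster_large(
            mat, K, table, n_runs=config.n_runs, seed=config.seed, workers=config.workers
        )
    else:
        cons = run_consensus(
            mat, K, table, n_runs=config.n_runs, base_seed=config.seed, workers=config.workers
        )
        labels = finalize_kmedoids(cons, K, seed=config.seed)
        assignment = assignment_from_labels(mat, labels, table)

    dist = cluster_distances(assignment, mat)
    if mat.capture_times is not None:
        graph = build_graph_timed(dist, assignment, mat.capture_times)
        t_map = cluster_pseudotimes_from_times(assignment, mat.capture_times)
        graph = direct_edges(graph, t_map)
    else:
        graph = build_graph(dist)
        start = 1
        t_map = cluster_pseudotimes_from_distances(graph, dist, start)
        graph = direct_edges(graph, t_map)

    genes = {
        (e.source, e.target): transition_genes(
            assignment, mat, table, (e.source, e.target), config.transition_threshold
        )
        for e in graph.edges
        if e.directed
    }
    ordering = assign_cells_to_edges(mat, assignment, graph, t_map)

    results = {
        "matrix": mat,
        "dropout": dropout,
        "table": table,
        "K": K,
        "assignment": assignment,
        "distances": dist,
        "graph": graph,
        "transition_genes": genes,
        "ordering": ordering,
    }
    _write_pipeline_outputs(results, config)
    return results


def _write_pipeline_outputs(results: dict, config: RunConfig) -> None:
    assignment = results["assignment"]
    graph = results["graph"]
    ordering = results["ordering"]
    mat = results["matrix"]

    def clusters_csv(path):
        pd.DataFrame({"cell_id": mat.cell_ids, "cluster": assignment.labels}).to_csv(
            path, index=False
        )

    def edges_tsv(path):
        pd.DataFrame(
            graph.to_edge_list(), columns=["source", "target", "distance", "directed"]
        ).to_csv(path, sep="\t", index=False)

    def distances_csv(path):
        pd.DataFrame(results["distances"].D).to_csv(path, index=False)

    def ordering_csv(path):
        df = ordering.to_frame()
        df["neg_loglik"] = -assignment.cell_loglik[
            np.arange(mat.n_cells), assignment.labels - 1
        ]
        df.to_csv(path, index=False)

    def genes_csv(path):
        rows = []
        for (a, b), res in results["transition_genes"].items():
            for rank, g in enumerate(res.order):
                rows.append(
                    {
                        "edge": f"{a}->{b}",
                        "rank": rank + 1,
                        "gene": res.gene_names[g],
                        "score": res.score[g],
                        "selected": bool(g in set(res.selected)),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    write_outputs(
        {
            "cluster": {"clusters.csv": clusters_csv},
            "lineage": {"edges.tsv": edges_tsv, "distances.csv": distances_csv},
            "genes": {"transition_genes.csv": genes_csv},
            "order": {"ordering.csv": ordering_csv},
        },
        config.out_dir,
        config=asdict(config),
    )
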