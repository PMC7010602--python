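# calista

Likelihood-based analysis of single-cell transcriptional profiles:
model-based clustering, lineage-graph inference, transition-gene
identification and pseudotemporal cell ordering, all built on one
mechanistic model of gene expression — the two-state (telegraph) model of
transcriptional bursting.  A reimplementation of the CALISTA toolkit in
scientific Python, with a synthetic-data module so every stage can be
exercised without downloading data.

It is aimed at researchers analysing differentiation time courses from
RT-qPCR, plate-based scRNA-seq (log RPKM/TPM) or droplet UMI counts who
want a single self-consistent probabilistic treatment from raw matrix to
ordered cells, rather than a pipeline of unrelated heuristics.

## The model

A gene's promoter switches between OFF and ON at rates θ_on and θ_off;
transcription proceeds at rate θ_t while ON; mRNA degrades with
first-order kinetics (all rates dimensionless, in units of the
degradation rate).  The steady-state mRNA count distribution is

    P₂(m; θ_on, θ_off, θ_t) =
        Γ(θ_on+m) Γ(θ_on+θ_off) θ_t^m
        ───────────────────────────────── · ₁F₁(θ_on+m, θ_on+θ_off+m, −θ_t)
        Γ(m+1) Γ(θ_on+θ_off+m) Γ(θ_on)

Random dropout is an exponential thinning: a true count m is read as zero
with probability e^(−λm).  Expression values are scaled per gene onto the
integer range [0, 200] and all likelihoods are exact lookups in a
precomputed table over a log-spaced (θ_on, θ_off, θ_t) grid, which makes
gene fitting an argmax and clustering a sequence of matrix products.

On this foundation:

- **Clustering** — greedy maximum-likelihood partitioning from many
  random starts, aggregated into a consensus matrix, finalized by PAM
  k-medoids; cluster number via the consensus-Laplacian eigengap; a
  best-run bypass for large datasets.
- **Lineage** — cluster distances d_kj = max(s_kk − s_kj, s_jj − s_jk)
  from cross-cluster likelihoods; greedy graph construction, or a
  directed variant using capture times (MAD outlier rule,
  feasible-parent selection); programmatic graph editing.
- **Transition genes** — per-edge gene scores
  v_g = v_g^j + v_g^k − v_g^{j+k}, the likelihood cost of merging two
  clusters, with a 50% cumulative-share selection rule.
- **Pseudotime** — cells allocated to lineage edges by maximizing an
  interpolated likelihood; path-wise ordering; per-cell likelihood
  landscape.
- **Trajectories** — moving-average gene profiles, signed Pearson
  co-expression networks, Bron–Kerbosch gene modules.
- **Synthetic data** — seeded generators for clustered telegraph counts,
  dropout, and a time-stamped two-bifurcation differentiation lineage
  with asynchronous commitment.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

Simulate the default bifurcating differentiation time course (1,800 cells,
12 genes, 9 capture times), cluster, infer the lineage and order cells:

```python
from calista import (
    build_param_table, simulate_lineage, cluster_distances,
    build_graph_timed, cluster_pseudotimes_from_times,
    assign_cells_to_edges, transition_genes, order_path,
)
from calista.clustering import cluster_large

table = build_param_table()                      # 2,880-point lookup table
mat, truth = simulate_lineage(seed=0)            # 1800 cells x 12 genes

assignment = cluster_large(mat, K=5, table=table, n_runs=20, seed=0)
dist = cluster_distances(assignment, mat)
graph = build_graph_timed(dist, assignment, mat.capture_times)
print([(e.source, e.target) for e in graph.edges])
# [(4, 1), (4, 5), (1, 2), (1, 3)]

t_map = cluster_pseudotimes_from_times(assignment, mat.capture_times)
ordering = assign_cells_to_edges(mat, assignment, graph, t_map)
cells = order_path(ordering, [4, 1, 2])
print(len(cells))
# 1228

res = transition_genes(assignment, mat, table, (1, 2))
print([res.gene_names[g] for g in res.selected])
# ['gene_8', 'gene_7', 'gene_6', 'gene_5', 'gene_4']
```

The recovered graph is the planted tree: cluster 4 (progenitors, t = 0)
branches into 5 (neurons) and 1 (glia, t = 0.4), and the glia cluster
branches into 2 and 3 (astrocytes and oligodendrocytes, t = 1.0) — two
bifurcations, matching the simulation design.  The 1,228 cells on the
path 4→1→2 are ordered along the astrocyte branch; the transition genes
selected on the glia→astrocyte edge are exactly the astrocyte markers
(genes 6–8) and the glia markers (genes 4–5), the genes whose expression
changes across that transition.  On this run the Spearman correlation
between recovered pseudotime and the true developmental time of
astrocyte-branch cells is 0.94.

The same stages are available from the shell:

```sh
calista simulate --preset cns --seed 0 --out sim/
calista preprocess --input sim/matrix.csv --format csv --data-type rnaseq --out prep.h5
calista cluster --input prep.h5 --k 5 --runs 20 --seed 0 --out clusters.csv
calista lineage --clusters clusters.csv --input prep.h5 --out lineage/
calista order --lineage lineage/ --clusters clusters.csv --input prep.h5 --path 4,1,2 --out order.csv
```

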