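"""Post-ordering trajectory analyses.

Moving-average gene expression along a pseudotemporally ordered path,
pairwise-correlation co-expression networks on the smoothed profiles, and
maximal-clique gene modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneTrajectory",
    "moving_average",
    "coexpression_network",
    "maximal_cliques",
]


@dataclass
class GeneTrajectory:
    """Smoothed expression of one gene along a developmental path."""

    gene: str
    pseudotimes: np.ndarray  # mean pseudotime of each window
    values: np.ndarray  # window means
    window: int

    def __len__(self) -> int:
        return self.values.size


def moving_average(
    expression: np.ndarray,
    pseudotimes: np.ndarray,
    gene_names: list[str],
    window_fraction: float = 0.1,
) -> list[GeneTrajectory]:
    """Sliding-window mean of each gene over pseudotime-ordered cells.

    ``expression`` is (n_cells, n_genes) in path order; the window holds
    ⌈window_fraction · n_cells⌉ cells and slides with stride 1.  The
    window's pseudotime is the mean pseudotime of its members.
    """
    expression = np.asarray(expression, dtype=float)
    pseudotimes = np.asarray(pseudotimes, dtype=float)
    n = expression.shape[0]
    if n < 10:
        raise ValueError("need at least 10 ordered cells")
    w = int(np.ceil(window_fraction * n))
    if w < 2:
        raise ValueError(f"window of {w} cells is too small")
    kernel = np.ones(w) / w
    t_smooth = np.convolve(pseudotimes, kernel, mode="valid")
    out = []
    for g, name in enumerate(gene_names):
        out.append(
            GeneTrajectory(
                gene=name,
                pseudotimes=t_smooth,
                values=np.convolve(expression[:, g], kernel, mode="valid"),
                window=w,
            )
        )
    return out


def coexpression_network(
    trajectories: list[GeneTrajectory],
    r_min: float = 0.8,
    p_max: float = 0.01,
):
    """Signed Pearson co-expression graph on smoothed trajectories.

    Genes are linked when |r| >= ``r_min`` and the two-sided p-value is at
    most ``p_max``; the edge carries r, p and sign(r) (negative
    correlations are part of the network).  Zero-variance trajectories are
    excluded with a warning.  Returns a networkx Graph.
    """
    import networkx as nx

    if len(trajectories) < 2:
        raise ValueError("need at least two gene trajectories")
    lengths = {len(t) for t in trajectories}
    if len(lengths) != 1:
        raise ValueError(f"trajectories have unequal lengths: {sorted(lengths)}")
    usable = []
    for t in trajectories:
        if np.std(t.values) == 0:
            warnings.warn(f"gene {t.gene} has a constant trajectory; excluded")
        else:
            usable.append(t)
    g = nx.Graph()
    g.add_nodes_from(t.gene for t in usable)
    for a, b in combinations(usable, 2):
        r, p = stats.pearsonr(a.values, b.values)
        if abs(r) >= r_min and p <= p_max:
            g.add_edge(a.gene, b.gene, r=float(r), p=float(p), sign=int(np.sign(r)))
    return g


def maximal_cliques(network, min_size: int = 5) -> list[list[str]]:
    """All maximal cliques of at least ``min_size`` genes.

    Bron–Kerbosch with pivoting (edge signs are ignored for cliquehood);
    output sorted by decreasing size, then lexicographically.
    """
    import networkx as nx

    cliques = [sorted(c) for c in nx.find_cliques(network) if len(c) >= min_size]
    return sorted(cliques, key=lambda c: (-len(c), c))
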