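"""Seeded synthetic single-cell data generators.

Produces data with the statistical structure the likelihood machinery
assumes: multi-cluster count matrices sampled from the steady-state
telegraph PMF, exponential-decay dropout, and a time-stamped bifurcating
differentiation lineage (a five-state tree modeled on central-nervous-
system differentiation: progenitors splitting into neurons and glia, glia
splitting into astrocytes and oligodendrocytes) with Gaussian
sampling-time jitter.  Every generator is deterministic given its seed and
emits ground truth alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burst_model import (
    DEFAULT_M_CAP,
    DropoutModel,
    TwoStateParams,
    _log_pmf_vector,
)
from .preprocess import ExpressionMatrix

__all__ = [
    "LineageSpec",
    "sample_two_state",
    "apply_dropout",
    "simulate_clusters",
    "simulate_lineage",
    "cns_preset",
]


def _pmf(params: TwoStateParams, m_cap: int) -> np.ndarray:
    """Renormalized PMF over 0..m_cap."""
    log_p = _log_pmf_vector(params, m_cap)
    p = np.exp(log_p - np.max(log_p[np.isfinite(log_p)]))
    p[~np.isfinite(log_p)] = 0.0
    return p / p.sum()


def sample_two_state(
    params: TwoStateParams, n: int, seed: int, m_cap: int = DEFAULT_M_CAP
) -> np.ndarray:
    """n i.i.d. draws from the truncated, renormalized telegraph PMF."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(m_cap + 1, size=n, p=_pmf(params, m_cap))


def apply_dropout(counts: np.ndarray, model: DropoutModel, seed: int) -> np.ndarray:
    """Zero each entry independently with probability e^(−λ·count)."""
    counts = np.asarray(counts)
    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        p_drop = np.exp(-model.lam * counts.astype(float))
    p_drop[counts == 0] = 1.0
    out = counts.copy()
    out[rng.random(counts.shape) < p_drop] = 0
    return out


def simulate_clusters(
    K: int,
    G: int,
    cells_per_cluster: int,
    params,
    seed: int = 0,
    m_cap: int = DEFAULT_M_CAP,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Block matrix of telegraph samples with ground-truth labels.

    ``params[k][g]`` gives the TwoStateParams of gene g in cluster k
    (0-based); returned labels are 1-based.  The output matrix is marked
    scaled (its values are already integer counts in PMF domain).
    """
    rng = np.random.default_rng(seed)
    n = K * cells_per_cluster
    values = np.zeros((n, G), dtype=np.int64)
    labels = np.repeat(np.arange(1, K + 1), cells_per_cluster)
    for k in range(K):
        rows = slice(k * cells_per_cluster, (k + 1) * cells_per_cluster)
        for g in range(G):
            p = _pmf(params[k][g], m_cap)
            values[rows, g] = rng.choice(m_cap + 1, size=cells_per_cluster, p=p)
    mat = ExpressionMatrix(
        values=values,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_names=[f"gene_{g}" for g in range(G)],
        data_kind="rnaseq_log",
        scaled=True,
    )
    return mat, labels


@dataclass
class LineageSpec:
    """Design of a time-stamped branching differentiation simulation.

    ``tree`` lists directed state transitions; ``state_params[state][g]``
    the telegraph parameters of each gene in each state; ``schedule`` maps
    each tree edge to the (start, end) simulation-time interval over which
    cells progress from the source state's expression program to the
    target's (parameters interpolated on log scale along the edge).  Cells
    with jittered times before the first transition express the root
    program unchanged.
    """

    states: list[str]
    tree: list[tuple[str, str]]
    state_params: dict
    schedule: dict  # edge -> (t_start, t_end)
    time_points: tuple = (0, 1, 2, 4, 6, 8, 12, 16, 20)
    cells_per_timepoint: int = 200
    jitter_sd: float = 0.2
    asynchrony_scale: float = 4.0
    root: str = field(default=None)

    def __post_init__(self) -> None:
        children: dict[str, list[str]] = {s: [] for s in self.states}
        parents = {}
        for a, b in self.tree:
            children[a].append(b)
            if b in parents:
                raise ValueError(f"state {b} has two parents; tree required")
            parents[b] = a
        roots = [s for s in self.states if s not in parents]
        if len(roots) != 1:
            raise ValueError(f"tree must have a single root, found {roots}")
        self.root = roots[0]
        self.children = children
        for e in self.tree:
            if e not in self.schedule:
                raise ValueError(f"edge {e} missing from schedule")

    @property
    def n_genes(self) -> int:
        return len(next(iter(self.state_params.values())))

    @property
    def t_max(self) -> float:
        return max(
            max(t1 for (_, t1) in self.schedule.values()),
            float(max(self.time_points)),
        )


def _marker_params(
    states: list[str],
    markers: dict[str, list[int]],
    G: int,
    theta_t_high: float = 150.0,
    theta_t_low: float = 15.0,
    theta_t_house: float = 40.0,
    theta_on: float = 2.0,
    theta_off: float = 1.0,
) -> dict:
    """Marker-gene parameter layout: each state's markers burst high."""
    assigned = {g for gl in markers.values() for g in gl}
    params = {}
    for s in states:
        row = []
        for g in range(G):
            if g in markers.get(s, []):
                tt = theta_t_high
            elif g in assigned:
                tt = theta_t_low
            else:
                tt = theta_t_house
            row.append(TwoStateParams(theta_on, theta_off, tt))
        params[s] = row
    return params


def cns_preset() -> LineageSpec:
    """Default bifurcating lineage: 12 genes, 5 states, 2 bifurcations.

    Progenitors (pCNS) differentiate into neurons and glia at t = 2; glia
    differentiate into astrocytes and oligodendrocytes (ODC) at t = 8.
    Nine capture times (0, 1, 2, 4, 6, 8, 12, 16, 20) with 200 cells each
    (1,800 total) and Gaussian sampling jitter of sd 0.2.  Each state has
    two high-bursting marker genes (θ_t = 150 vs. 5 elsewhere); two
    housekeeping genes are constant across states.
    """
    states = ["pCNS", "neuron", "glia", "astrocyte", "ODC"]
    tree = [("pCNS", "neuron"), ("pCNS", "glia"), ("glia", "astrocyte"), ("glia", "ODC")]
    markers = {
        "pCNS": [0, 1],
        "neuron": [2, 3],
        "glia": [4, 5],
        "astrocyte": [6, 7, 8],
        "ODC": [9, 10, 11],
    }
    schedule = {
        ("pCNS", "neuron"): (2.0, 3.0),
        ("pCNS", "glia"): (2.0, 3.0),
        ("glia", "astrocyte"): (8.0, 9.0),
        ("glia", "ODC"): (8.0, 9.0),
    }
    return LineageSpec(
        states=states,
        tree=tree,
        state_params=_marker_params(states, markers, G=12),
        schedule=schedule,
    )


def _interp_params(a: TwoStateParams, b: TwoStateParams, f: float) -> TwoStateParams:
    """Log-scale linear interpolation between two parameter triples."""
    def mix(x, y):
        return float(np.exp((1 - f) * np.log(x) + f * np.log(y)))

    return TwoStateParams(
        mix(a.theta_on, b.theta_on),
        mix(a.theta_off, b.theta_off),
        mix(a.theta_t, b.theta_t),
    )


def _leaf_paths(spec: LineageSpec) -> list[list[str]]:
    paths = []

    def walk(state, acc):
        kids = spec.children[state]
        if not kids:
            paths.append(acc)
        for c in kids:
            walk(c, acc + [c])

    walk(spec.root, [spec.root])
    return paths


def simulate_lineage(
    spec: LineageSpec | None = None,
    seed: int = 0,
    m_cap: int = DEFAULT_M_CAP,
    n_interp: int = 25,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Time-stamped single-cell counts along a branching lineage.

    For each nominal capture time the sampling time of every cell is drawn
    from Normal(t_i, jitter_sd).  Differentiation is asynchronous: each
    cell carries an exponential commitment delay (mean
    ``spec.asynchrony_scale``), so its developmental time is the sampling
    time minus its delay (clipped to the simulated interval) — later
    states therefore accumulate cells at later captures, as in real
    time-course data.  Each cell follows one leaf path (uniform branch
    choice at every bifurcation); its per-gene parameters are interpolated
    on log scale along the tree edge containing its developmental time
    (PMFs pre-computed at ``n_interp`` knots per edge), and counts are
    drawn from the resulting telegraph PMF.  Returns the matrix (nominal
    capture times attached) and a truth table with columns cell_id,
    capture_time, true_time (developmental), leaf, state, edge, position.
    """
    if spec is None:
        spec = cns_preset()
    rng = np.random.default_rng(seed)
    G = spec.n_genes
    t_max = spec.t_max

    # PMF knots per edge and per gene (plus root-state PMFs)
    root_pmf = np.stack([_pmf(spec.state_params[spec.root][g], m_cap) for g in range(G)])
    edge_pmf = {}
    fracs = np.linspace(0.0, 1.0, n_interp)
    for (a, b) in spec.tree:
        knots = np.empty((n_interp, G, m_cap + 1))
        for i, f in enumerate(fracs):
            for g in range(G):
                knots[i, g] = _pmf(
                    _interp_params(spec.state_params[a][g], spec.state_params[b][g], f),
                    m_cap,
                )
        edge_pmf[(a, b)] = knots

    paths = _leaf_paths(spec)
    n_total = len(spec.time_points) * spec.cells_per_timepoint
    values = np.zeros((n_total, G), dtype=np.int64)
    rows = []
    i = 0
    clipped = 0
    for tp in spec.time_points:
        for _ in range(spec.cells_per_timepoint):
            t_sample = rng.normal(tp, spec.jitter_sd)
            delay = (
                rng.exponential(spec.asynchrony_scale)
                if spec.asynchrony_scale > 0
                else 0.0
            )
            t_true = max(t_sample - delay, 0.0)  # cells cannot predate the start
            if t_true > t_max:
                clipped += 1
                t_true = t_max
            # choose a leaf path by a fair coin at each bifurcation
            path = [spec.root]
            state = spec.root
            while spec.children[state]:
                kids = spec.children[state]
                state = kids[rng.integers(len(kids))] if len(kids) > 1 else kids[0]
                path.append(state)
            # locate the edge (along this path) containing t_true
            edge = None
            frac = 0.0
            for a, b in zip(path[:-1], path[1:]):
                t0, t1 = spec.schedule[(a, b)]
                if t_true >= t0:
                    edge = (a, b)
                    frac = min((t_true - t0) / (t1 - t0), 1.0)
            if edge is None:
                values[i] = [
                    rng.choice(m_cap + 1, p=root_pmf[g]) for g in range(G)
                ]
                state_lab, edge_lab, pos = spec.root, "", 0.0
            else:
                ki = int(round(frac * (n_interp - 1)))
                pmfs = edge_pmf[edge][ki]
                values[i] = [rng.choice(m_cap + 1, p=pmfs[g]) for g in range(G)]
                state_lab = edge[1] if frac >= 0.5 else edge[0]
                edge_lab = f"{edge[0]}->{edge[1]}"
                pos = frac
            rows.append(
                {
                    "cell_id": f"cell_{i}",
                    "capture_time": float(tp),
                    "true_time": float(t_true),
                    "leaf": path[-1],
                    "state": state_lab,
                    "edge": edge_lab,
                    "position": float(pos),
                }
            )
            i += 1
    if clipped:
        warnings.warn(f"{clipped} jittered times clipped to [0, {t_max}]")
    truth = pd.DataFrame(rows)
    mat = ExpressionMatrix(
        values=values,
        cell_ids=list(truth["cell_id"]),
        gene_names=[f"gene_{g}" for g in range(G)],
        capture_times=truth["capture_time"].to_numpy(),
        data_kind="rnaseq_log",
        scaled=True,
    )
    return mat, truth
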