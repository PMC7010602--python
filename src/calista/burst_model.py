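"""Steady-state two-state (telegraph) transcription model likelihoods.

The two-state model describes a promoter stochastically switching between an
inactive (OFF) and active (ON) state, with transcription only while ON and
first-order mRNA degradation.  All rates are nondimensionalized by the mRNA
degradation rate constant, leaving three parameters: the promoter activation
rate ``theta_on``, inactivation rate ``theta_off`` and transcription rate
``theta_t``.  The stationary mRNA copy-number distribution is

    P2(m) = [Γ(θon+m) Γ(θon+θoff) θt^m] /
            [Γ(m+1) Γ(θon+θoff+m) Γ(θon)] · ₁F₁(θon+m, θon+θoff+m, −θt)

with ₁F₁ the confluent hypergeometric function of the first kind.  This
module evaluates that PMF in log space, combines it with an exponential
random-dropout model, tabulates it over a parameter grid, and performs
table-based maximum-likelihood fitting — the numerical core every other
module calls.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "TwoStateParams",
    "DropoutModel",
    "NO_DROPOUT",
    "ParamTable",
    "steady_state_log_pmf",
    "dropout_prob",
    "observed_log_pmf",
    "build_param_table",
    "default_grid",
    "fit_mle",
    "cell_log_likelihood",
]

#: default maximum supported (scaled) count
DEFAULT_M_CAP = 200

#: pre-renormalization tail mass above which a grid point is flagged
TAIL_MASS_TOL = 1e-3


class NumericsError(ArithmeticError):
    """Raised when the PMF evaluation produces a non-finite result."""


@dataclass(frozen=True)
class TwoStateParams:
    """Dimensionless rates of the two-state transcription model.

    ``theta_t = 0`` is accepted as the degenerate no-transcription limit
    (all probability mass at zero counts).
    """

    theta_on: float
    theta_off: float
    theta_t: float

    def __post_init__(self) -> None:
        for name in ("theta_on", "theta_off"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")
        if not (np.isfinite(self.theta_t) and self.theta_t >= 0):
            raise ValueError(f"theta_t must be nonnegative and finite, got {self.theta_t}")


@dataclass(frozen=True)
class DropoutModel:
    """Exponential random-dropout model P(observe 0 | true count m) = e^(−λm).

    ``lam = 0`` means every measurement drops out; ``lam = inf`` is the
    no-dropout sentinel (dropout probability 0 for any positive count).
    """

    lam: float

    def __post_init__(self) -> None:
        if np.isnan(self.lam) or self.lam < 0:
            raise ValueError(f"dropout decay constant must be >= 0, got {self.lam}")

    @property
    def is_no_dropout(self) -> bool:
        return np.isinf(self.lam)


NO_DROPOUT = DropoutModel(lam=np.inf)


def _check_counts(m, name: str = "m") -> np.ndarray:
    arr = np.asarray(m)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{name} must be numeric")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    if not np.all(arr == np.floor(arr)):
        raise ValueError(f"{name} must be integer-valued")
    return arr.astype(np.int64)


def _log_kummer_series(c: float, b: np.ndarray, z: float) -> np.ndarray:
    """log ₁F₁(c, b, z) for z >= 0, c > 0, vectorized over b.

    All series terms are positive, so the sum is a plain logsumexp of
    log-terms; the j-th log-term is built from cumulative sums of the
    rising-factorial logs.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if z == 0:
        return np.zeros_like(b)
    # series terms peak near j ~ z; 10-sigma Poisson-style tail margin
    n_terms = int(np.ceil(z + 10.0 * np.sqrt(z + 1.0) + 60.0))
    j = np.arange(n_terms, dtype=float)
    log_num = np.concatenate(([0.0], np.cumsum(np.log(c + j[:-1]))))
    # (b)_j in log, per b value: shape (len(b), n_terms)
    log_den = np.concatenate(
        (np.zeros((b.size, 1)), np.cumsum(np.log(b[:, None] + j[None, :-1]), axis=1)),
        axis=1,
    )
    log_terms = log_num[None, :] - log_den + j[None, :] * np.log(z) - gammaln(j + 1.0)[None, :]
    return logsumexp(log_terms, axis=1)


def _log_pmf_vector(params: TwoStateParams, m_max: int) -> np.ndarray:
    """ln P2(m) for m = 0..m_max (un-renormalized)."""
    on, off, t = params.theta_on, params.theta_off, params.theta_t
    m = np.arange(m_max + 1, dtype=float)
    if t == 0:
        out = np.full(m_max + 1, -np.inf)
        out[0] = 0.0
        return out
    b = on + off + m
    # Kummer transform: 1F1(on+m, b, -t) = e^{-t} 1F1(off, b, t)
    log_f = -t + _log_kummer_series(off, b, t)
    log_p = (
        gammaln(on + m)
        + gammaln(on + off)
        - gammaln(m + 1.0)
        - gammaln(b)
        - gammaln(on)
        + m * np.log(t)
        + log_f
    )
    if not np.all(np.isfinite(log_p)):
        log_p = _mpmath_log_pmf_vector(params, m_max, log_p)
    return log_p


def _mpmath_log_pmf_vector(
    params: TwoStateParams, m_max: int, partial: np.ndarray
) -> np.ndarray:
    """Arbitrary-precision fallback for mass points the series lost."""
    import mpmath

    on, off, t = params.theta_on, params.theta_off, params.theta_t
    out = partial.copy()
    bad = np.where(~np.isfinite(partial))[0]
    for m in bad:
        with mpmath.workdps(50):
            val = (
                mpmath.loggamma(on + m)
                + mpmath.loggamma(on + off)
                - mpmath.loggamma(m + 1)
                - mpmath.loggamma(on + off + m)
                - mpmath.loggamma(on)
                + m * mpmath.log(t)
                + mpmath.log(mpmath.hyp1f1(on + m, on + off + m, -t))
            )
        out[m] = float(val)
    if not np.all(np.isfinite(out)):
        raise NumericsError(
            f"non-finite PMF at params (theta_on={on}, theta_off={off}, theta_t={t})"
        )
    return out


def steady_state_log_pmf(params: TwoStateParams, m) -> float | np.ndarray:
    """ln P2(m; θon, θoff, θt), the stationary telegraph-model log-PMF.

    Accepts a scalar count or an integer array; returns matching shape.
    ``theta_t = 0`` puts all mass at m = 0 (log-probability −inf for m > 0).
    """
    scalar = np.isscalar(m) or np.ndim(m) == 0
    arr = _check_counts(np.atleast_1d(m))
    vec = _log_pmf_vector(params, int(arr.max()))
    out = vec[arr]
    return float(out[0]) if scalar else out


def dropout_prob(model: DropoutModel, m) -> float | np.ndarray:
    """Dropout probability e^(−λm) of observing zero given true count m."""
    scalar = np.isscalar(m) or np.ndim(m) == 0
    arr = np.atleast_1d(np.asarray(m, dtype=float))
    if np.any(arr < 0):
        raise ValueError("m must be nonnegative")
    with np.errstate(invalid="ignore"):
        out = np.exp(-model.lam * arr)
    # inf * 0 -> treat e^{-inf*0} as 1 (m = 0 is always "observed zero")
    out[arr == 0] = 1.0
    return float(out[0]) if scalar else out


def _apply_dropout_to_log_pmf(log_pmf: np.ndarray, lam: float) -> np.ndarray:
    """Fold the dropout mixture into a (renormalized) log-PMF row.

    Observed-count distribution: the zero bin collects Σ_m e^(−λm) P2(m);
    positive bins are thinned by (1 − e^(−λm)).  Sums to 1 whenever the
    input row does.
    """
    if np.isinf(lam):
        return log_pmf.copy()
    m = np.arange(log_pmf.shape[-1], dtype=float)
    out = np.empty_like(log_pmf)
    out[..., 0] = logsumexp(log_pmf - lam * m, axis=-1)
    with np.errstate(divide="ignore"):
        log_keep = np.log1p(-np.exp(-lam * m[1:]))
    out[..., 1:] = log_pmf[..., 1:] + log_keep
    return out


def observed_log_pmf(
    params: TwoStateParams,
    model: DropoutModel,
    m_hat,
    m_cap: int = DEFAULT_M_CAP,
) -> float | np.ndarray:
    """Log-PMF of the *measured* count under the dropout-thinned model.

    The zero-truncation sum runs over m = 0..m_cap.
    """
    scalar = np.isscalar(m_hat) or np.ndim(m_hat) == 0
    arr = _check_counts(np.atleast_1d(m_hat), name="m_hat")
    top = max(int(arr.max()), m_cap)
    vec = _apply_dropout_to_log_pmf(_log_pmf_vector(params, top), model.lam)
    out = vec[arr]
    return float(out[0]) if scalar else out


@dataclass
class ParamTable:
    """Pre-computed log-PMF lookup table over a parameter grid.

    ``log_pmf[i, m]`` is the renormalized log-probability of count ``m``
    under grid point ``i``; each row sums to one over ``0..m_cap``.  When a
    finite-λ dropout model is supplied at build time, the dropout mixture
    is baked into every row so that downstream fitting is a pure lookup.
    """

    theta_on: np.ndarray  # (P,)
    theta_off: np.ndarray  # (P,)
    theta_t: np.ndarray  # (P,)
    log_pmf: np.ndarray  # (P, m_cap + 1)
    m_cap: int
    dropout: DropoutModel | None = None
    tail_flagged: np.ndarray = field(default=None)  # (P,) bool
    grid_spec: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.log_pmf.shape[0]

    def params_at(self, i: int) -> TwoStateParams:
        return TwoStateParams(
            float(self.theta_on[i]), float(self.theta_off[i]), float(self.theta_t[i])
        )

    def loglik_per_point(self, counts: np.ndarray) -> np.ndarray:
        """Σ_n log P(counts_n; θ_i) for every grid point i (shape (P,))."""
        counts = _check_counts(counts, "counts")
        if counts.max() > self.m_cap:
            raise ValueError(f"counts exceed table m_cap={self.m_cap}")
        hist = np.bincount(counts, minlength=self.m_cap + 1).astype(float)
        return self.log_pmf @ hist

    def loglik_from_histogram(self, hist: np.ndarray) -> np.ndarray:
        """Like :meth:`loglik_per_point` but from per-count histograms.

        ``hist`` has shape (m_cap + 1,) or (m_cap + 1, G); result has shape
        (P,) or (P, G).
        """
        return self.log_pmf @ hist

    def content_hash(self) -> str:
        lam = self.dropout.lam if self.dropout is not None else None
        key = json.dumps(
            {
                "theta_on": self.theta_on.tolist(),
                "theta_off": self.theta_off.tolist(),
                "theta_t": self.theta_t.tolist(),
                "m_cap": self.m_cap,
                "lam": None if lam is None else float(lam),
            },
            sort_keys=True,
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["m_cap"] = self.m_cap
            f.attrs["content_hash"] = self.content_hash()
            f.attrs["lam"] = (
                np.nan if self.dropout is None else float(self.dropout.lam)
            )
            for name in ("theta_on", "theta_off", "theta_t", "log_pmf", "tail_flagged"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load(cls, path) -> "ParamTable":
        import h5py

        with h5py.File(path, "r") as f:
            lam = float(f.attrs["lam"])
            dropout = None if np.isnan(lam) else DropoutModel(lam)
            return cls(
                theta_on=f["theta_on"][:],
                theta_off=f["theta_off"][:],
                theta_t=f["theta_t"][:],
                log_pmf=f["log_pmf"][:],
                m_cap=int(f.attrs["m_cap"]),
                dropout=dropout,
                tail_flagged=f["tail_flagged"][:].astype(bool),
            )


def default_grid() -> dict:
    """Default log-spaced parameter grid.

    θ_on, θ_off span 0.01–100 (12 values each); θ_t spans 1–400 (20
    values), so the PMF mean covers the full 0–200 scaled-count range from
    strongly bursty to near-constitutive regimes.
    """
    return {
        "theta_on": np.logspace(-2, 2, 12),
        "theta_off": np.logspace(-2, 2, 12),
        "theta_t": np.logspace(0, np.log10(400.0), 20),
    }


#: memory guard for table construction
_MAX_TABLE_BYTES = 2 * 1024**3


def build_param_table(
    grid_spec: dict | None = None,
    m_cap: int = DEFAULT_M_CAP,
    dropout: DropoutModel | None = None,
) -> ParamTable:
    """Tabulate the renormalized log-PMF on a cartesian parameter grid.

    Each row is Eq.-normalized over the truncated support 0..m_cap; grid
    points whose untruncated tail mass exceeds ``TAIL_MASS_TOL`` are
    flagged (their likelihoods remain usable but the truncation is
    material there).  Deterministic given its inputs.
    """
    if grid_spec is None:
        grid_spec = default_grid()
    axes = {k: np.asarray(grid_spec[k], dtype=float) for k in ("theta_on", "theta_off", "theta_t")}
    for name, vals in axes.items():
        if vals.size == 0:
            raise ValueError(f"grid axis {name} is empty")
        if np.any(vals <= 0):
            raise ValueError(f"grid axis {name} must be strictly positive")
    if m_cap < 1:
        raise ValueError("m_cap must be >= 1")
    n_points = axes["theta_on"].size * axes["theta_off"].size * axes["theta_t"].size
    nbytes = n_points * (m_cap + 1) * 8
    if nbytes > _MAX_TABLE_BYTES:
        raise MemoryError(
            f"parameter table would need {nbytes / 1e9:.1f} GB "
            f"({n_points} grid points x {m_cap + 1} counts)"
        )

    on_g, off_g, t_g = np.meshgrid(
        axes["theta_on"], axes["theta_off"], axes["theta_t"], indexing="ij"
    )
    on_f, off_f, t_f = on_g.ravel(), off_g.ravel(), t_g.ravel()
    log_pmf = np.empty((n_points, m_cap + 1))
    for i in range(n_points):
        log_pmf[i] = _log_pmf_vector(
            TwoStateParams(on_f[i], off_f[i], t_f[i]), m_cap
        )
    row_logsum = logsumexp(log_pmf, axis=1)
    tail_flagged = (1.0 - np.exp(row_logsum)) > TAIL_MASS_TOL
    log_pmf -= row_logsum[:, None]
    if dropout is not None and not dropout.is_no_dropout:
        log_pmf = _apply_dropout_to_log_pmf(log_pmf, dropout.lam)
    return ParamTable(
        theta_on=on_f,
        theta_off=off_f,
        theta_t=t_f,
        log_pmf=log_pmf,
        m_cap=m_cap,
        dropout=dropout,
        tail_flagged=tail_flagged,
        grid_spec={k: v.tolist() for k, v in axes.items()},
    )


def fit_mle(counts, table: ParamTable) -> tuple[TwoStateParams, float]:
    """Exact table-grid maximum-likelihood fit for one gene's counts.

    Returns the grid point maximizing Σ_n log P(m̂_n; θ) and that maximum.
    Ties resolve to the lowest grid index (deterministic).
    """
    ll = table.loglik_per_point(np.asarray(counts))
    i = int(np.argmax(ll))
    return table.params_at(i), float(ll[i])


def cell_log_likelihood(
    cell_counts,
    params_per_gene: list[TwoStateParams],
    model: DropoutModel | None = None,
    m_cap: int = DEFAULT_M_CAP,
) -> float:
    """Λ of one cell: Σ_g log P(m̂_g; θ_g), additive over genes."""
    counts = _check_counts(np.asarray(cell_counts), "cell_counts")
    if counts.shape[0] != len(params_per_gene):
        raise ValueError(
            f"{counts.shape[0]} counts but {len(params_per_gene)} parameter triples"
        )
    total = 0.0
    for m, p in zip(counts, params_per_gene):
        if model is None or model.is_no_dropout:
            total += steady_state_log_pmf(p, int(m))
        else:
            total += observed_log_pmf(p, model, int(m), m_cap=m_cap)
    return float(total)
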