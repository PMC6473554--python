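"""Per-node conjugate dynamic linear models.

A multiregression dynamic model (MDM) decomposes an n-dimensional time
series into n univariate dynamic regressions: each node (brain region) is
regressed on the *contemporaneous* values of its parent nodes, with
coefficients that follow a Gaussian random walk and an unknown observation
precision handled conjugately (normal--gamma).  The state innovation
covariance is specified through a single discount factor ``delta`` per node
model: the prior coefficient covariance is inflated by ``1/delta`` at every
step, so ``delta = 1`` recovers a static-coefficient Bayesian regression.

The model-selection score for a parent set is the log predictive likelihood
(LPL): the sum over time of the one-step-ahead Student-t forecast log
densities.  The LPL of a full network is the sum of its n per-node local
scores, so log Bayes factors between networks are differences of LPLs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


__all__ = [
    "SubjectSeries",
    "NodePrior",
    "PriorPolicy",
    "FilterResult",
    "SmoothedEstimates",
    "standardize",
    "build_regressors",
    "filter_node",
    "filter_best_delta",
    "smooth_node",
    "local_score",
    "DEFAULT_DELTA_GRID",
]

#: Discount grid searched when scoring a parent set; the score of a parent
#: set is the maximum LPL over this grid.
DEFAULT_DELTA_GRID: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95, 0.99, 1.00)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectSeries:
    """One subject's T x n observation matrix with named regions."""

    subject_id: str
    values: np.ndarray
    region_names: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_names", tuple(self.region_names))
        if values.ndim != 2:
            raise ValueError("values must be a T x n matrix")
        if values.shape[0] < 2:
            raise ValueError("need at least T = 2 time points")
        if values.shape[1] != len(self.region_names):
            raise ValueError("region_names length must match number of columns")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite values in series {self.subject_id!r}")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NodePrior:
    """Initial information for one node model.

    ``m0`` is the prior coefficient mean, ``C0 = c0_scale * I`` the prior
    coefficient covariance, and the observation precision has a
    Gamma(n0/2, d0/2) prior.  ``delta`` is the discount factor implementing
    the coefficient random walk.
    """

    m0: np.ndarray
    c0_scale: float = 3.0
    n0: float = 0.001
    d0: float = 0.001
    delta: float = 1.0

    def __post_init__(self):
        m0 = np.atleast_1d(np.asarray(self.m0, dtype=float))
        object.__setattr__(self, "m0", m0)
        if self.c0_scale <= 0:
            raise ValueError("c0_scale must be positive")
        if self.n0 <= 0 or self.d0 <= 0:
            raise ValueError("n0 and d0 must be positive")
        if not (0 < self.delta <= 1):
            raise ValueError("delta must lie in (0, 1]")


@dataclass(frozen=True)
class PriorPolicy:
    """How node models are specified and scored across a study.

    The same policy must be used for every model being compared: the LPL is
    only a valid model-selection score when priors, discount grid and
    burn-in agree across candidates.
    """

    c0_scale: float = 3.0
    n0: float = 0.001
    d0: float = 0.001
    delta_grid: tuple[float, ...] = DEFAULT_DELTA_GRID
    burn_in: int = 0
    standardize: bool = True

    def __post_init__(self):
        object.__setattr__(self, "delta_grid", tuple(float(d) for d in self.delta_grid))
        if not self.delta_grid:
            raise ValueError("delta_grid must be nonempty")
        for d in self.delta_grid:
            if not (0 < d <= 1):
                raise ValueError("every delta must lie in (0, 1]")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")

    def node_prior(self, p: int, delta: float) -> NodePrior:
        return NodePrior(
            m0=np.zeros(p), c0_scale=self.c0_scale, n0=self.n0, d0=self.d0, delta=delta
        )


@dataclass(frozen=True)
class FilterResult:
    """Forward (Kalman) filter output for one node model."""

    means: np.ndarray  # (T, p) filtered coefficient means m_t
    covs: np.ndarray  # (T, p, p) filtered coefficient scale matrices C_t
    ns: np.ndarray  # (T,) precision shape counts n_t
    ds: np.ndarray  # (T,) precision rate counts d_t
    loglik: np.ndarray  # (T,) one-step Student-t forecast log densities
    delta: float
    prior: NodePrior

    @property
    def total(self) -> float:
        """Sum of the per-time forecast log densities (the LPL summand)."""
        return float(self.loglik.sum())

    def total_after(self, burn_in: int = 0) -> float:
        return float(self.loglik[burn_in:].sum())

    @property
    def point_variances(self) -> np.ndarray:
        return np.einsum("tii->ti", self.covs)


@dataclass(frozen=True)
class SmoothedEstimates:
    """Backward-smoothed coefficient trajectories and time averages."""

    means: np.ndarray  # (T, p) smoothed means
    variances: np.ndarray  # (T, p) smoothed marginal variances
    theta_bar: np.ndarray  # (p,) time-average of smoothed means
    var_bar: np.ndarray  # (p,) time-average of smoothed variances
    delta: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def standardize(series: SubjectSeries) -> SubjectSeries:
    """Scale every column to mean 0 and sample standard deviation 1."""
    y = series.values
    mu = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    bad = ~(sd > 0)
    if np.any(bad):
        names = [series.region_names[j] for j in np.flatnonzero(bad)]
        raise ValueError(
            f"cannot standardize constant column(s) {names} in series "
            f"{series.subject_id!r}"
        )
    return replace(series, values=(y - mu) / sd, standardized=True)


def build_regressors(series: SubjectSeries, r: int, parents: Iterable[int]) -> np.ndarray:
    """Design matrix for node ``r``: an intercept column followed by the
    contemporaneous parent series in the given order."""
    parents = list(parents)
    if r in parents:
        raise ValueError(f"node {r} cannot be its own parent (self-loop)")
    T = series.T
    F = np.empty((T, 1 + len(parents)))
    F[:, 0] = 1.0
    for k, p in enumerate(parents):
        F[:, 1 + k] = series.values[:, p]
    return F


def _filter_loop(y, F, m0, c0_scale, n0, d0, delta):
    """Conjugate DLM forward recurrences with discounted evolution.

    Tracks the on-line scaled coefficient covariance C_t (already multiplied
    by the current point estimate S_t = d_t / n_t of the observation
    variance), so the one-step forecast of y_t is Student-t with n_{t-1}
    degrees of freedom, location F_t' m_{t-1} and squared scale
    q_t = F_t' (C_{t-1}/delta) F_t + S_{t-1}.
    """
    T = y.shape[0]
    p = F.shape[1]
    means = np.empty((T, p))
    covs = np.empty((T, p, p))
    ns = np.empty(T)
    ds = np.empty(T)
    loglik = np.empty(T)

    m = m0.copy()
    S0 = d0 / n0
    C = np.eye(p) * (c0_scale * S0)
    n = n0
    d = d0
    S = S0
    R = np.empty((p, p))
    Rf = np.empty(p)
    A = np.empty(p)
    for t in range(T):
        # evolution: R_t = C_{t-1} / delta
        f = 0.0
        for i in range(p):
            f += F[t, i] * m[i]
            acc = 0.0
            for j in range(p):
                R[i, j] = C[i, j] / delta
                acc += R[i, j] * F[t, j]
            Rf[i] = acc
        q = S
        for i in range(p):
            q += F[t, i] * Rf[i]
        e = y[t] - f
        # one-step Student-t forecast density, df = n
        loglik[t] = (
            math.lgamma(0.5 * (n + 1.0))
            - math.lgamma(0.5 * n)
            - 0.5 * math.log(n * math.pi * q)
            - 0.5 * (n + 1.0) * math.log1p(e * e / (n * q))
        )
        n1 = n + 1.0
        d1 = d + S * e * e / q
        S1 = d1 / n1
        ratio = S1 / S
        for i in range(p):
            A[i] = Rf[i] / q
        for i in range(p):
            m[i] = m[i] + A[i] * e
            for j in range(p):
                C[i, j] = ratio * (R[i, j] - A[i] * A[j] * q)
        n = n1
        d = d1
        S = S1
        for i in range(p):
            means[t, i] = m[i]
            for j in range(p):
                covs[t, i, j] = C[i, j]
        ns[t] = n
        ds[t] = d
    return means, covs, ns, ds, loglik


_filter_loop_py = _filter_loop
if _HAVE_NUMBA:
    _filter_loop = _njit(cache=True, fastmath=False)(_filter_loop)


def filter_node(y: np.ndarray, F: np.ndarray, prior: NodePrior) -> FilterResult:
    """Run the conjugate DLM forward filter for one node model.

    Parameters
    ----------
    y : (T,) observation vector for the node.
    F : (T, p) regressor matrix (see :func:`build_regressors`).
    prior : initial information, including the discount factor.

    Returns
    -------
    FilterResult with per-time filtered moments, precision counts and the
    per-time one-step Student-t forecast log densities.
    """
    y = np.ascontiguousarray(y, dtype=float)
    F = np.ascontiguousarray(F, dtype=float)
    if y.ndim != 1 or F.ndim != 2 or F.shape[0] != y.shape[0]:
        raise ValueError("y must be (T,) and F must be (T, p)")
    if prior.m0.shape[0] != F.shape[1]:
        raise ValueError("prior mean length must equal the number of regressors")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(F))):
        raise ValueError("non-finite values in filter input")
    means, covs, ns, ds, loglik = _filter_loop(
        y, F, np.ascontiguousarray(prior.m0, dtype=float),
        prior.c0_scale, prior.n0, prior.d0, prior.delta,
    )
    if not np.all(np.isfinite(loglik)):
        raise FloatingPointError("numerical failure: non-finite forecast density")
    return FilterResult(means=means, covs=covs, ns=ns, ds=ds, loglik=loglik,
                        delta=prior.delta, prior=prior)


def smooth_node(filt: FilterResult) -> SmoothedEstimates:
    """Backward (retrospective) smoothing of the coefficient trajectory.

    With an identity evolution matrix and discounted evolution the smoother
    gain is the constant ``delta``, so the recursion reduces to

        a~_t = m_t + delta * (a~_{t+1} - m_t)
        R~_t = C_t + delta^2 * (R~_{t+1} - C_t / delta)

    and the retrospective scale matrices are rescaled by S_T / S_t so all
    variances refer to the final observation-variance estimate.
    """
    T, p = filt.means.shape
    if T == 0:
        raise ValueError("cannot smooth an empty (partial) filter result")
    delta = filt.delta
    sm = np.empty((T, p))
    sv = np.empty((T, p))
    S = filt.ds / filt.ns
    a = filt.means[T - 1].copy()
    R = filt.covs[T - 1].copy()
    sm[T - 1] = a
    sv[T - 1] = np.diag(R)
    for t in range(T - 2, -1, -1):
        m_t = filt.means[t]
        C_t = filt.covs[t]
        a = m_t + delta * (a - m_t)
        R = C_t + delta * delta * (R - C_t / delta)
        sm[t] = a
        sv[t] = np.diag(R) * (S[T - 1] / S[t])
    if np.any(sv <= 0):
        sv = np.maximum(sv, np.finfo(float).tiny)
    return SmoothedEstimates(
        means=sm, variances=sv,
        theta_bar=sm.mean(axis=0), var_bar=sv.mean(axis=0), delta=delta,
    )


def filter_best_delta(
    series: SubjectSeries, r: int, parents: Sequence[int], policy: PriorPolicy
) -> FilterResult:
    """Filter node ``r`` at every grid discount and keep the best-LPL fit."""
    F = build_regressors(series, r, parents)
    y = series.values[:, r]
    best: FilterResult | None = None
    best_score = -math.inf
    for delta in policy.delta_grid:
        fr = filter_node(y, F, policy.node_prior(F.shape[1], delta))
        score = fr.total_after(policy.burn_in)
        if score > best_score:
            best, best_score = fr, score
    assert best is not None
    return best


def local_score(
    series: SubjectSeries,
    r: int,
    parents: Iterable[int],
    policy: PriorPolicy | None = None,
) -> float:
    """Local LPL score c(r, Pa) of node ``r`` under the given parent set.

    The score is the maximum over the policy's discount grid of the summed
    one-step forecast log densities (skipping ``burn_in`` initial terms).
    It is invariant to the ordering of ``parents``.
    """
    policy = policy or PriorPolicy()
    parents = sorted(set(parents))
    fr = filter_best_delta(series, r, parents, policy)
    return fr.total_after(policy.burn_in)
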