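"""Agent-side Bayesian machinery: posterior expected utilities and choice thresholds.

The k-th decider holds a private estimate ``Uhat_k`` of its own utility
difference ``U_k`` and has observed the choices ``C_1..C_{k-1}``.  Its
posterior is

    p(U_k | Uhat_k, history)  ∝  phi(U_k) phi((Uhat_k - U_k)/eps) P(history | U_k),

where the likelihood of the history is the probability that each earlier
private estimate fell on the side of that agent's own critical value matching
its observed choice — a multivariate-normal rectangle probability under the
conditional law of (Uhat_1..Uhat_{k-1}) given U_k.  The agent chooses A iff
its own estimate exceeds the critical value Uhat* at which the posterior mean
of U_k is zero; the empty-history threshold is exactly 0.  Critical values are
defined recursively through the thresholds of every earlier agent, which is
what the threshold tables memoise.

With cryptic subtypes the likelihood is additionally marginalised over the
putative type sequence of earlier deciders, each weighted by its prior
frequency, and each earlier agent's threshold is the one that agent would
itself compute knowing its own type but marginalising over earlier types.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .model import (
    ALPHA,
    BETA,
    ChoiceHistory,
    ModelParams,
    SubtypeSpec,
    as_history,
    all_histories,
    type_sequences,
)
from .numerics import _gh_nodes, monotone_root, rectangle_probabilities

__all__ = [
    "ThresholdTable",
    "SubtypeThresholdTable",
    "posterior_mean_second",
    "posterior_mean_general",
    "posterior_mean_subtype",
    "critical_value",
    "critical_value_subtype",
    "build_threshold_table",
    "build_subtype_threshold_table",
]

_N_NODES = 64
_ROOT_TOL = 1e-8

HistoryLike = Union[str, Sequence[int], ChoiceHistory]


def _gaussian_envelope(u_hat: float, eps: float) -> tuple[float, float]:
    """Mean and sd of the no-social-information posterior p(U | Uhat)."""
    var = eps**2 / (1.0 + eps**2)
    return u_hat / (1.0 + eps**2), np.sqrt(var)


def _history_bounds(history: ChoiceHistory, thresholds: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Integration box over (Uhat_1..Uhat_m): above the threshold for A, below for B."""
    m = len(history)
    lo = np.full(m, -np.inf)
    hi = np.full(m, np.inf)
    for j, (choice, t) in enumerate(zip(history, thresholds)):
        if choice > 0:
            lo[j] = t
        else:
            hi[j] = t
    return lo, hi


def _likelihood_on_nodes(
    u_nodes: np.ndarray,
    history: ChoiceHistory,
    corr_to_focal: np.ndarray,
    cond_cov: np.ndarray,
    thresholds: Sequence[float],
    n_points: int,
) -> np.ndarray:
    """P(history | U_k = u) on a vector of utility nodes.

    ``corr_to_focal[j] = cov(Uhat_j, U_k)``; given U_k the earlier estimates
    are jointly normal with mean ``corr_to_focal * u`` and covariance
    ``cond_cov``, so the likelihood is a rectangle probability with bounds
    shifted per node.
    """
    lo, hi = _history_bounds(history, thresholds)
    shift = np.outer(u_nodes, corr_to_focal)  # (B, m)
    return rectangle_probabilities(lo[None, :] - shift, hi[None, :] - shift, cond_cov, n_points=n_points)


def _homogeneous_conditional(history_len: int, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """(corr_to_focal, conditional covariance) of earlier estimates given U_k.

    Derived mechanically from the joint covariance: cov(Uhat_j, U_k) = rho,
    var(Uhat_j | U_k) = 1 + eps^2 - rho^2, cov(Uhat_j, Uhat_l | U_k) = rho - rho^2.
    """
    m = history_len
    rho, eps = params.rho, params.eps
    corr_to_focal = np.full(m, rho)
    cond = np.full((m, m), rho - rho**2)
    np.fill_diagonal(cond, 1.0 + eps**2 - rho**2)
    return corr_to_focal, cond


class ThresholdTable:
    """Memoised critical values Uhat* for a homogeneous population.

    Keys are choice histories; ``table[history]`` is the threshold the next
    decider applies after observing that history.  Entries are computed on
    demand (recursively over prefixes).  Mirrored histories are solved once:
    swapping A and B flips the sign of every threshold exactly, so the table
    canonicalises on histories whose first choice is A.
    """

    def __init__(self, params: ModelParams, n_nodes: int = _N_NODES,
                 n_points: int | None = None, root_tol: float = _ROOT_TOL):
        self.params = params
        self.n_nodes = n_nodes
        self.n_points = n_points
        self.root_tol = root_tol
        self._cache: dict[ChoiceHistory, float] = {ChoiceHistory(): 0.0}

    def __getitem__(self, history: HistoryLike) -> float:
        h = as_history(history)
        if h in self._cache:
            return self._cache[h]
        if h[0] < 0:  # canonical form starts with A
            val = -self[h.mirror()]
        else:
            val = critical_value(h, self.params, self, n_nodes=self.n_nodes,
                                 n_points=self.n_points, tol=self.root_tol)
        self._cache[h] = val
        return val

    get = __getitem__

    def prefix_thresholds(self, history: HistoryLike) -> list[float]:
        """Thresholds applied by each of the deciders recorded in ``history``."""
        h = as_history(history)
        return [self[p] for p in h.prefixes()]

    def __contains__(self, history: HistoryLike) -> bool:
        return as_history(history) in self._cache

    def __len__(self) -> int:
        return len(self._cache)


def _kernel_points(n_points: int | None) -> int:
    from .numerics import _DEFAULT_POINTS

    return _DEFAULT_POINTS if n_points is None else n_points


def posterior_mean_general(
    u_hat: float,
    history: HistoryLike,
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
    n_nodes: int = _N_NODES,
    n_points: int | None = None,
) -> float:
    """E(U_k | Uhat_k = u_hat, C_1..C_{k-1}) for the next decider.

    With an empty history this reduces to the conjugate shrinkage
    ``u_hat / (1 + eps^2)``; with one previous choice it reproduces the
    second decider's posterior mean.  Strictly increasing in ``u_hat``.
    """
    h = as_history(history)
    mu, sd = _gaussian_envelope(u_hat, params.eps)
    if len(h) == 0 or params.rho == 0.0:
        # zero correlation: earlier choices carry no information about U_k
        return mu
    if thresholds is None:
        thresholds = ThresholdTable(params, n_nodes=n_nodes, n_points=n_points)
    pre = thresholds.prefix_thresholds(h)
    x, w = _gh_nodes(n_nodes)
    u = mu + sd * x
    corr_to_focal, cond = _homogeneous_conditional(len(h), params)
    like = _likelihood_on_nodes(u, h, corr_to_focal, cond, pre, _kernel_points(n_points))
    denom = float(w @ like)
    if denom <= 0.0:
        raise FloatingPointError(f"history {h} has vanishing probability at u_hat={u_hat}")
    return float(w @ (u * like)) / denom


def posterior_mean_second(
    u_hat: float,
    first_choice: int,
    params: ModelParams,
    n_nodes: int = _N_NODES,
    n_points: int | None = None,
) -> float:
    """Posterior mean of U_2 given the private estimate and the first choice.

    Special case of :func:`posterior_mean_general` with a length-one history;
    the social factor is Phi(U_2 * C_1 * rho / sqrt(1 + eps^2 - rho^2)).
    """
    if first_choice not in (-1, 1):
        raise ValueError("first_choice must be +1 (A) or -1 (B)")
    return posterior_mean_general(u_hat, ChoiceHistory((first_choice,)), params,
                                  n_nodes=n_nodes, n_points=n_points)


def critical_value(
    history: HistoryLike,
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
    n_nodes: int = _N_NODES,
    n_points: int | None = None,
    tol: float = _ROOT_TOL,
) -> float:
    """Critical private estimate Uhat* at which the posterior mean is zero.

    The next decider chooses A iff its estimate strictly exceeds this value
    (ties resolve to B).  Negative after histories favouring A when rho > 0.
    """
    h = as_history(history)
    if len(h) == 0 or params.rho == 0.0:
        return 0.0
    if thresholds is None:
        thresholds = ThresholdTable(params, n_nodes=n_nodes, n_points=n_points, root_tol=tol)

    def f(u: float) -> float:
        return posterior_mean_general(u, h, params, thresholds,
                                      n_nodes=n_nodes, n_points=n_points)

    return monotone_root(f, tol=tol)


def build_threshold_table(
    n_agents: int,
    params: ModelParams,
    n_nodes: int = _N_NODES,
    n_points: int | None = None,
) -> ThresholdTable:
    """Thresholds for every decider in a group of ``n_agents``.

    Precomputes all histories of length 0..n_agents-1 (the last agent
    conditions on n_agents-1 earlier choices), in prefix order.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    table = ThresholdTable(params, n_nodes=n_nodes, n_points=n_points)
    for m in range(n_agents):
        for h in all_histories(m):
            table[h]
    return table


# ---------------------------------------------------------------------------
# Cryptic subtypes
# ---------------------------------------------------------------------------


def _subtype_conditional(
    focal_type: str,
    prev_types: Sequence[str],
    spec: SubtypeSpec,
    eps: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(corr_to_focal, conditional covariance) for one putative type sequence."""
    r_focal = np.array([spec.corr(focal_type, t) for t in prev_types])
    m = len(prev_types)
    cond = np.empty((m, m))
    for j in range(m):
        for l in range(m):
            base = 1.0 + eps**2 if j == l else spec.corr(prev_types[j], prev_types[l])
            cond[j, l] = base - r_focal[j] * r_focal[l]
    return r_focal, cond


class SubtypeThresholdTable:
    """Memoised cryptic-type critical values, keyed by (own type, history).

    Every agent knows its own type but marginalises over the types of all
    earlier deciders, so one threshold per (type, history) pair suffices no
    matter which putative sequence it appears in.  Mirror antisymmetry holds
    per type and is exploited exactly as in the homogeneous table.
    """

    def __init__(self, spec: SubtypeSpec, params: ModelParams,
                 n_nodes: int = _N_NODES, n_points: int | None = None,
                 root_tol: float = _ROOT_TOL):
        self.spec = spec
        self.params = params
        self.n_nodes = n_nodes
        self.n_points = n_points
        self.root_tol = root_tol
        empty = ChoiceHistory()
        self._cache: dict[tuple[str, ChoiceHistory], float] = {
            (ALPHA, empty): 0.0,
            (BETA, empty): 0.0,
        }

    def __getitem__(self, key: tuple[str, HistoryLike]) -> float:
        own_type, history = key
        h = as_history(history)
        k = (own_type, h)
        if k in self._cache:
            return self._cache[k]
        if h[0] < 0:
            val = -self[(own_type, h.mirror())]
        else:
            val = critical_value_subtype(h, own_type, self.spec, self.params, self,
                                         n_nodes=self.n_nodes, n_points=self.n_points,
                                         tol=self.root_tol)
        self._cache[k] = val
        return val

    def prefix_thresholds(self, history: HistoryLike, prev_types: Sequence[str]) -> list[float]:
        h = as_history(history)
        return [self[(t, p)] for t, p in zip(prev_types, h.prefixes())]


def posterior_mean_subtype(
    u_hat: float,
    history: HistoryLike,
    focal_type: str,
    spec: SubtypeSpec,
    params: ModelParams,
    table: SubtypeThresholdTable | None = None,
    n_nodes: int = _N_NODES,
    n_points: int | None = None,
) -> float:
    """Posterior mean of U_k for a focal agent of known type, cryptic others.

    The history likelihood is a mixture over putative type sequences s of the
    earlier deciders, weighted by gamma**n_alpha * (1-gamma)**n_beta, each
    term a rectangle probability under that sequence's covariance and the
    type-specific thresholds of the earlier agents.
    """
    h = as_history(history)
    mu, sd = _gaussian_envelope(u_hat, params.eps)
    if len(h) == 0:
        return mu
    if table is None:
        table = SubtypeThresholdTable(spec, params, n_nodes=n_nodes, n_points=n_points)
    x, w = _gh_nodes(n_nodes)
    u = mu + sd * x
    like = np.zeros_like(u)
    for prev_types, weight in type_sequences(len(h), spec.gamma):
        r_focal, cond = _subtype_conditional(focal_type, prev_types, spec, params.eps)
        pre = table.prefix_thresholds(h, prev_types)
        like += weight * _likelihood_on_nodes(u, h, r_focal, cond, pre, _kernel_points(n_points))
    denom = float(w @ like)
    if denom <= 0.0:
        raise FloatingPointError(f"history {h} has vanishing probability at u_hat={u_hat}")
    return float(w @ (u * like)) / denom


def critical_value_subtype(
    history: HistoryLike,
    focal_type: str,
    spec: SubtypeSpec,
    params: ModelParams,
    table: SubtypeThresholdTable | None = None,
    n_nodes: int = _N_NODES,
    n_points: int | None = None,
    tol: float = _ROOT_TOL,
) -> float:
    """Critical value for a focal agent of the given type under cryptic subtypes."""
    h = as_history(history)
    if len(h) == 0:
        return 0.0
    if table is None:
        table = SubtypeThresholdTable(spec, params, n_nodes=n_nodes, n_points=n_points,
                                      root_tol=tol)

    def f(u: float) -> float:
        return posterior_mean_subtype(u, h, focal_type, spec, params, table,
                                      n_nodes=n_nodes, n_points=n_points)

    return monotone_root(f, tol=tol)


def build_subtype_threshold_table(
    n_agents: int,
    spec: SubtypeSpec,
    params: ModelParams,
    n_nodes: int = _N_NODES,
    n_points: int | None = None,
) -> SubtypeThresholdTable:
    """Cryptic-type thresholds for both types and all histories up to length n_agents-1."""
    table = SubtypeThresholdTable(spec, params, n_nodes=n_nodes, n_points=n_points)
    for m in range(n_agents):
        for h in all_histories(m):
            for t in (ALPHA, BETA):
                table[(t, h)]
    return table
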