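"""External-observer computations.

An observer records the agents' choices under an experimental noise level
``eta`` that may differ from the habitual level ``eps`` the agents' decision
rules are calibrated to.  Agents still apply their eps-calibrated thresholds,
but the private estimates that actually cross those thresholds are generated
with noise eta.  Probabilities of whole choice sequences are therefore
rectangle probabilities of (Uhat_1..Uhat_m) under the eta-generative joint,
with each coordinate bounded at that agent's own threshold, above for A and
below for B.  Conditional next-choice probabilities are ratios of two such
sequence probabilities.

Two distinct next-choice quantities are provided and should not be confused:

* :func:`conditional_choice_probability` — the exact conditional
  P(C_next = A | C_1..C_m) under the generative joint.  Because utilities are
  correlated across agents, observing the history shifts the focal agent's
  own estimate too; this is the quantity an experimenter estimates by
  filtering recorded sequences, and the one the Monte-Carlo simulator
  reproduces.
* :func:`focal_response_probability` — the response curve of a focal agent
  whose utility is drawn fresh from the prior, facing a *fixed* observed
  history: Phi(-Uhat*_h / sqrt(1 + eta^2)).  The history enters only through
  the critical value, so successive decisions are treated as independent
  given the threshold cascade.  This is the quantity behind the package's
  figure-style response sweeps; it returns to exactly 0.5 whenever the
  threshold vanishes (e.g. in the low-noise limit), and its P = 0.5 contour
  does not depend on the experimental noise level.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .inference import (
    SubtypeThresholdTable,
    ThresholdTable,
    build_subtype_threshold_table,
    build_threshold_table,
)
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
from .numerics import rectangle_probabilities

__all__ = [
    "OutcomeDistribution",
    "rsw",
    "consensus_score",
    "sequence_probability",
    "conditional_choice_probability",
    "focal_response_probability",
    "sequence_probability_subtype",
    "conditional_choice_probability_subtype",
    "focal_response_probability_subtype",
    "outcome_distribution",
]

_MIN_HISTORY_PROB = 1e-12
_MAX_ENUM_AGENTS = 10

HistoryLike = Union[str, Sequence[int], ChoiceHistory]


def rsw(rho: float, eps: float) -> float:
    """Relative social weighting: rho * eps / sqrt(1 + eps^2 - rho^2).

    The ratio of the weight a rational second decider places on the first
    choice versus its own private information.  Equals 1 for identical
    preferences (rho = 1), 0 for uncorrelated preferences, tends to rho for
    eps >> 1 and to 0 for eps -> 0 (private information dominates when
    reliable); negative rho gives a negative RSW (active avoidance).
    """
    denom = 1.0 + eps**2 - rho**2
    if denom <= 0.0:
        raise ValueError("1 + eps^2 - rho^2 must be positive (degenerate at eps=0, |rho|=1)")
    return rho * eps / np.sqrt(denom)


def consensus_score(n_a: int, n_b: int) -> float:
    """|n_A - n_B| / (n_A + n_B): 1 = unanimity, 0 = even split."""
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    total = n_a + n_b
    if total == 0:
        raise ValueError("consensus score undefined for an empty group")
    return abs(n_a - n_b) / total


def _observer_cov(m: int, rho: float, eta: float) -> np.ndarray:
    cov = np.full((m, m), rho)
    np.fill_diagonal(cov, 1.0 + eta**2)
    return cov


def _sequence_box(choices: ChoiceHistory, thresholds: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    m = len(choices)
    lo = np.full(m, -np.inf)
    hi = np.full(m, np.inf)
    for j, (c, t) in enumerate(zip(choices, thresholds)):
        if c > 0:
            lo[j] = t
        else:
            hi[j] = t
    return lo, hi


def sequence_probability(
    choices: HistoryLike,
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
    n_points: int | None = None,
) -> float:
    """P(C_1..C_m) from the observer's perspective.

    Thresholds are calibrated with eps (the agents' rule); the generative
    joint uses eta.  The empty sequence has probability 1.
    """
    h = as_history(choices)
    if len(h) == 0:
        return 1.0
    if thresholds is None:
        thresholds = ThresholdTable(params)
    # prefix_thresholds yields the threshold each recorded decider applied
    lo, hi = _sequence_box(h, thresholds.prefix_thresholds(h))
    cov = _observer_cov(len(h), params.rho, params.eta)
    kwargs = {} if n_points is None else {"n_points": n_points}
    return float(rectangle_probabilities(lo, hi, cov, **kwargs)[0])


def conditional_choice_probability(
    history: HistoryLike,
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
    n_points: int | None = None,
) -> float:
    """P(next choice = A | observed history), as a ratio of sequence probabilities.

    Computed as P(h+A) / (P(h+A) + P(h+B)): identical to dividing by P(h)
    exactly, but self-consistent under quadrature so that the probabilities
    of the two continuations always sum to one.
    """
    h = as_history(history)
    if thresholds is None:
        thresholds = ThresholdTable(params)
    p_a = sequence_probability(h.extended(1), params, thresholds, n_points=n_points)
    p_b = sequence_probability(h.extended(-1), params, thresholds, n_points=n_points)
    denom = p_a + p_b
    if denom < _MIN_HISTORY_PROB:
        raise ValueError(f"history {h} has probability {denom:.3g}; conditional undefined")
    return p_a / denom


def focal_response_probability(
    history: HistoryLike,
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
) -> float:
    """P(focal agent chooses A | fixed history), utility drawn from the prior.

    The observed history determines the critical value Uhat*_h; the focal
    agent's private estimate is marginally N(0, 1 + eta^2), so the response
    is Phi(-Uhat*_h / sqrt(1 + eta^2)).  Unlike
    :func:`conditional_choice_probability` the focal estimate is not
    conditioned on the history through the utility correlation, so this is
    the per-decision response curve, exactly 0.5 whenever the threshold is
    zero and sharper for lower experimental noise.
    """
    h = as_history(history)
    if thresholds is None:
        thresholds = ThresholdTable(params)
    from scipy.special import ndtr

    return float(ndtr(-thresholds[h] / np.sqrt(1.0 + params.eta**2)))


def focal_response_probability_subtype(
    history: HistoryLike,
    focal_type: str,
    spec: SubtypeSpec,
    params: ModelParams,
    table: SubtypeThresholdTable | None = None,
) -> float:
    """Per-decision response curve for a focal agent of known cryptic type."""
    if focal_type not in (ALPHA, BETA):
        raise ValueError(f"focal_type must be {ALPHA!r} or {BETA!r}")
    h = as_history(history)
    if table is None:
        table = SubtypeThresholdTable(spec, params)
    from scipy.special import ndtr

    return float(ndtr(-table[(focal_type, h)] / np.sqrt(1.0 + params.eta**2)))


def sequence_probability_subtype(
    choices: HistoryLike,
    spec: SubtypeSpec,
    params: ModelParams,
    table: SubtypeThresholdTable | None = None,
    focal_type: str | None = None,
    n_points: int | None = None,
) -> float:
    """Observer-side P(C_1..C_m), marginalising the deciders' cryptic types.

    If ``focal_type`` is given, the last decider's type is fixed to it (its
    prior weight excluded) while all earlier types are marginalised — the
    building block for type-conditional choice probabilities.
    """
    h = as_history(choices)
    m = len(h)
    if m == 0:
        return 1.0
    if table is None:
        table = SubtypeThresholdTable(spec, params)
    kwargs = {} if n_points is None else {"n_points": n_points}
    n_marg = m - 1 if focal_type is not None else m
    total = 0.0
    for prev_types, weight in type_sequences(n_marg, spec.gamma):
        types = prev_types + (focal_type,) if focal_type is not None else prev_types
        thr = table.prefix_thresholds(h, types)
        lo, hi = _sequence_box(h, thr)
        cov = np.empty((m, m))
        for j in range(m):
            for l in range(m):
                cov[j, l] = 1.0 + params.eta**2 if j == l else spec.corr(types[j], types[l])
        total += weight * float(rectangle_probabilities(lo, hi, cov, **kwargs)[0])
    return total


def conditional_choice_probability_subtype(
    history: HistoryLike,
    focal_type: str,
    spec: SubtypeSpec,
    params: ModelParams,
    table: SubtypeThresholdTable | None = None,
    n_points: int | None = None,
) -> float:
    """P(next = A | history, focal agent's type), cryptic earlier types.

    Earlier deciders' types are marginalised both in the thresholds and in
    the generative covariance; the focal agent's type is conditioned on.
    Since types are drawn independently, the history's marginal probability
    does not depend on the focal type.
    """
    if focal_type not in (ALPHA, BETA):
        raise ValueError(f"focal_type must be {ALPHA!r} or {BETA!r}")
    h = as_history(history)
    if table is None:
        table = SubtypeThresholdTable(spec, params)
    p_a = sequence_probability_subtype(h.extended(1), spec, params, table,
                                       focal_type=focal_type, n_points=n_points)
    p_b = sequence_probability_subtype(h.extended(-1), spec, params, table,
                                       focal_type=focal_type, n_points=n_points)
    denom = p_a + p_b
    if denom < _MIN_HISTORY_PROB:
        raise ValueError(f"history {h} has probability {denom:.3g}; conditional undefined")
    return p_a / denom


class OutcomeDistribution:
    """Probability over the final count n_A of A-choosers in a group of N."""

    def __init__(self, n_agents: int, probs: np.ndarray):
        probs = np.asarray(probs, float)
        if probs.shape != (n_agents + 1,):
            raise ValueError("need one probability per count 0..N")
        total = probs.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"outcome probabilities sum to {total:.8f}, not 1")
        self.n_agents = n_agents
        self.probs = probs

    def probability(self, n_a: int) -> float:
        return float(self.probs[n_a])

    def expected_consensus(self) -> float:
        n = self.n_agents
        scores = np.array([consensus_score(k, n - k) for k in range(n + 1)])
        return float(self.probs @ scores)

    def __repr__(self) -> str:
        return f"OutcomeDistribution(N={self.n_agents}, E[consensus]={self.expected_consensus():.4f})"


def outcome_distribution(
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
    n_points: int | None = None,
    method: str = "joint",
) -> OutcomeDistribution:
    """Distribution of the final count n_A by enumerating all 2^N sequences.

    ``method="joint"`` (default) sums exact sequence probabilities: one
    rectangle probability per full sequence, with the 2^N leaf boxes sharing
    the N x N observer covariance so they are evaluated in a single batched
    kernel call.  ``method="chain"`` instead multiplies per-decision focal
    response probabilities down each branch (decisions independent given the
    threshold cascade), the cheaper pipeline behind the figure-style
    consensus surfaces.  The two coincide exactly at rho = 0.  Limited to
    N <= 10.
    """
    n = params.n_agents
    if n > _MAX_ENUM_AGENTS:
        raise ValueError(f"exhaustive enumeration limited to N <= {_MAX_ENUM_AGENTS}")
    if method not in ("joint", "chain"):
        raise ValueError("method must be 'joint' or 'chain'")
    if thresholds is None:
        thresholds = build_threshold_table(n, params)
    seqs = all_histories(n)
    if method == "chain":
        probs = np.zeros(n + 1)
        for s in seqs:
            p = 1.0
            for m in range(n):
                p_a = focal_response_probability(ChoiceHistory(s.signs[:m]), params, thresholds)
                p *= p_a if s[m] > 0 else 1.0 - p_a
            probs[sum(1 for c in s if c > 0)] += p
        return OutcomeDistribution(n, probs)
    lo = np.empty((len(seqs), n))
    hi = np.empty((len(seqs), n))
    for i, s in enumerate(seqs):
        lo[i], hi[i] = _sequence_box(s, thresholds.prefix_thresholds(s))
    cov = _observer_cov(n, params.rho, params.eta)
    kwargs = {} if n_points is None else {"n_points": n_points}
    leaf = rectangle_probabilities(lo, hi, cov, **kwargs)
    probs = np.zeros(n + 1)
    for s, p in zip(seqs, leaf):
        n_a = sum(1 for c in s if c > 0)
        probs[n_a] += p
    total = probs.sum()
    if abs(total - 1.0) > 1e-5:
        raise FloatingPointError(f"sequence probabilities sum to {total:.8f}")
    return OutcomeDistribution(n, probs / total)
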