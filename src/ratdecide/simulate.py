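"""Monte-Carlo generative simulator: the brute-force oracle for the exact engine.

Every exact probability (sequence probabilities, conditional choice
probabilities, posterior means) has a paired empirical estimate here, obtained
by drawing utilities and private estimates from the generative model and
applying the sequential threshold rule replicate by replicate.  A factor-level
generator additionally rebuilds the covariance structure from first principles
(explicit weight vectors over environmental factors) rather than from the
closed-form joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .inference import SubtypeThresholdTable, ThresholdTable
from .model import (
    ALPHA,
    BETA,
    ChoiceHistory,
    FactorLevelSpec,
    ModelParams,
    SubtypeSpec,
    as_history,
    utility_correlation_matrix,
)

__all__ = [
    "SimulationRun",
    "simulate_group",
    "simulate_subtype_group",
    "simulate_factor_level",
    "empirical_sequence_probability",
    "empirical_conditional_probability",
    "posterior_mean_mc",
]

HistoryLike = Union[str, Sequence[int], ChoiceHistory]


@dataclass
class SimulationRun:
    """Raw output of a group simulation.

    ``choices`` has one row per replicate, entries ±1 (A = +1); ``types`` is
    None for homogeneous runs, else an array of type labels per seat.
    """

    params: ModelParams
    seed: int
    choices: np.ndarray = field(repr=False)
    types: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_reps(self) -> int:
        return self.choices.shape[0]

    def sequence_frequency(self, sequence: HistoryLike) -> tuple[float, float]:
        """Empirical P(C_1..C_m) over the first m seats, with binomial stderr."""
        s = np.array(as_history(sequence).signs)
        m = len(s)
        hits = np.all(self.choices[:, :m] == s, axis=1)
        p = hits.mean()
        return float(p), float(np.sqrt(p * (1.0 - p) / self.n_reps))

    def conditional_frequency(self, history: HistoryLike,
                              focal_type: str | None = None) -> tuple[float, float]:
        """Empirical P(next = A | history [, focal type]) with stderr."""
        h = np.array(as_history(history).signs)
        m = len(h)
        if self.choices.shape[1] <= m:
            raise ValueError("simulation has no decider after this history")
        mask = np.all(self.choices[:, :m] == h, axis=1) if m else np.ones(self.n_reps, bool)
        if focal_type is not None:
            if self.types is None:
                raise ValueError("run has no type assignments")
            mask &= self.types[:, m] == focal_type
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"history {as_history(history)} never occurred in the run")
        p = float((self.choices[mask, m] > 0).mean())
        return p, float(np.sqrt(p * (1.0 - p) / n))


def _draw_joint(corr: np.ndarray, eta: float, n_reps: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (U, Uhat) with Uhat = U + eta * z, independent z per agent.

    At the utility level the estimate residuals are independent across
    agents, which reproduces cov(Uhat_k, Uhat_l) = corr_kl + eta^2 delta_kl.
    """
    n = corr.shape[0]
    w, V = np.linalg.eigh(corr)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    U = rng.standard_normal((n_reps, n)) @ root.T
    Uhat = U + eta * rng.standard_normal((n_reps, n))
    return U, Uhat


def _apply_sequential_rule(Uhat: np.ndarray, threshold_fn) -> np.ndarray:
    """Sequential choices: seat k chooses A iff Uhat_k strictly exceeds the
    threshold for its observed history (ties go to B)."""
    n_reps, n = Uhat.shape
    choices = np.empty((n_reps, n), dtype=np.int8)
    for k in range(n):
        if k == 0:
            groups = {(): np.arange(n_reps)}
        else:
            groups = {}
            keys = [tuple(row) for row in choices[:, :k]]
            for i, key in enumerate(keys):
                groups.setdefault(key, []).append(i)
        for hist, idx in groups.items():
            idx = np.asarray(idx)
            t = threshold_fn(k, ChoiceHistory(hist), idx)
            if np.isscalar(t):
                choices[idx, k] = np.where(Uhat[idx, k] > t, 1, -1)
            else:
                choices[idx, k] = np.where(Uhat[idx, k] > np.asarray(t), 1, -1)
    return choices


def simulate_group(
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
    n_reps: int = 100_000,
    seed: int = 0,
) -> SimulationRun:
    """Simulate a homogeneous group making one ordered sequence of choices.

    Utilities are drawn from the prior MVN with correlation rho; private
    estimates add eta-scale noise (the experimental level); each seat applies
    its eps-calibrated threshold in sequence.  Bitwise reproducible for a
    given seed.
    """
    if thresholds is None:
        thresholds = ThresholdTable(params)
    rng = np.random.default_rng(seed)
    corr = utility_correlation_matrix(params)
    _, Uhat = _draw_joint(corr, params.eta, n_reps, rng)
    choices = _apply_sequential_rule(Uhat, lambda k, h, idx: thresholds[h])
    return SimulationRun(params=params, seed=seed, choices=choices)


def simulate_subtype_group(
    spec: SubtypeSpec,
    params: ModelParams,
    table: SubtypeThresholdTable | None = None,
    n_reps: int = 100_000,
    seed: int = 0,
) -> SimulationRun:
    """Simulate a group with cryptic subtypes.

    Types are drawn i.i.d. (alpha with probability gamma) per seat and
    replicate; utilities use the type-assignment covariance; each agent
    applies its own-type, type-marginalised threshold.
    """
    if table is None:
        table = SubtypeThresholdTable(spec, params)
    rng = np.random.default_rng(seed)
    n = params.n_agents
    types = np.where(rng.random((n_reps, n)) < spec.gamma, ALPHA, BETA)
    Uhat = np.empty((n_reps, n))
    # group replicates by type pattern so each pattern uses one covariance
    patterns = {}
    for i, row in enumerate(map(tuple, types)):
        patterns.setdefault(row, []).append(i)
    for pattern, idx in patterns.items():
        idx = np.asarray(idx)
        corr = utility_correlation_matrix(spec, pattern)
        sub_rng = np.random.default_rng(rng.integers(2**31))
        _, Uhat[idx] = _draw_joint(corr, params.eta, len(idx), sub_rng)

    def threshold_fn(k: int, hist: ChoiceHistory, idx: np.ndarray) -> np.ndarray:
        t_alpha = table[(ALPHA, hist)]
        t_beta = table[(BETA, hist)]
        return np.where(types[idx, k] == ALPHA, t_alpha, t_beta)

    choices = _apply_sequential_rule(Uhat, threshold_fn)
    return SimulationRun(params=params, seed=seed, choices=choices, types=types)


def simulate_factor_level(
    spec: FactorLevelSpec,
    eps: float,
    n_reps: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Empirical covariance of (U_1..U_N, Uhat_1..Uhat_N) from explicit factors.

    Draws standard-normal factor differences x_i and per-agent, per-factor
    noise residuals of scale eps, forms utilities and private estimates
    through the weight vectors, and returns the 2N x 2N sample covariance —
    a first-principles check of the closed-form joint.
    """
    if not eps > 0:
        raise ValueError("eps must be strictly positive")
    rng = np.random.default_rng(seed)
    W = spec.weight_vectors  # (n_factors, n_agents)
    nf, n = W.shape
    x = rng.standard_normal((n_reps, nf))
    U = x @ W
    nu = rng.standard_normal((n_reps, nf, n)) * eps
    Uhat = U + np.einsum("rfk,fk->rk", nu, W)
    Z = np.concatenate([U, Uhat], axis=1)
    return np.cov(Z, rowvar=False)


def empirical_sequence_probability(run: SimulationRun, sequence: HistoryLike) -> tuple[float, float]:
    return run.sequence_frequency(sequence)


def empirical_conditional_probability(run: SimulationRun, history: HistoryLike,
                                      focal_type: str | None = None) -> tuple[float, float]:
    return run.conditional_frequency(history, focal_type)


def posterior_mean_mc(
    u_hat: float,
    history: HistoryLike,
    params: ModelParams,
    thresholds: ThresholdTable | None = None,
    n_reps: int = 1_000_000,
    delta: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Rejection-sampling estimate of E(U_k | Uhat_k ≈ u_hat, history).

    Samples the joint of (U_k, Uhat_1..Uhat_k) under the agents' internal
    model (noise eps), keeps replicates whose earlier estimates fall in the
    history's threshold box and whose own estimate lies within ±delta of
    ``u_hat``, and averages U_k.  Returns (estimate, standard error).
    """
    h = as_history(history)
    k = len(h)
    if thresholds is None:
        thresholds = ThresholdTable(params)
    pre = thresholds.prefix_thresholds(h)
    rng = np.random.default_rng(seed)
    n = k + 1
    corr = np.full((n, n), params.rho)
    np.fill_diagonal(corr, 1.0)
    U, Uhat = _draw_joint(corr, params.eps, n_reps, rng)
    mask = np.abs(Uhat[:, k] - u_hat) <= delta
    for j, (c, t) in enumerate(zip(h, pre)):
        mask &= (Uhat[:, j] > t) if c > 0 else (Uhat[:, j] <= t)
    kept = U[mask, k]
    if kept.size < 2:
        raise ValueError("too few accepted samples; increase n_reps or delta")
    return float(kept.mean()), float(kept.std(ddof=1) / np.sqrt(kept.size))
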