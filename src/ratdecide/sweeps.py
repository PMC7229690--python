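"""Tidy-table parameter sweeps over noise levels and preference correlations.

Each function returns a pandas DataFrame with one row per parameter/history
combination, in deterministic order (lexicographic in parameters, then
history), mirroring the package's CSV output contract.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import (
    SubtypeThresholdTable,
    ThresholdTable,
)
from .model import ALPHA, BETA, ChoiceHistory, ModelParams, SubtypeSpec, all_histories
from .observer import (
    conditional_choice_probability,
    focal_response_probability,
    focal_response_probability_subtype,
    outcome_distribution,
    rsw,
)
from .simulate import simulate_group

__all__ = [
    "default_histories",
    "eps_grid",
    "conditional_sweep",
    "conflict_sweep",
    "consensus_sweep",
    "subtype_sweep",
    "simulation_check",
    "SUBTYPE_PRESETS",
]

#: The two-type scenarios studied in the package's worked examples: equally
#: prevalent types with identical within-type preferences and independent
#: between-type preferences, and a 90/10 majority/minority split with high
#: within-type and low between-type alignment.
SUBTYPE_PRESETS = {
    "equal_split": SubtypeSpec(gamma=0.5, rho_high=1.0, rho_low=0.0),
    "majority_minority": SubtypeSpec(gamma=0.9, rho_high=0.9, rho_low=0.25),
}


def default_histories(max_len: int = 3) -> list[ChoiceHistory]:
    """All non-empty histories up to the given length (14 for max_len=3)."""
    out: list[ChoiceHistory] = []
    for m in range(1, max_len + 1):
        out.extend(all_histories(m))
    return out


def eps_grid(lo: float = 0.1, hi: float = 10.0, n: int = 9, log: bool = True) -> np.ndarray:
    """Default environmental-noise grid, logarithmic to span both the
    private-information-dominated and social-information-dominated regimes."""
    if n < 1:
        raise ValueError("grid must be non-empty")
    if log:
        if lo <= 0:
            raise ValueError("log grid needs lo > 0")
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


def conditional_sweep(
    rho: float,
    eps_values: Iterable[float],
    eta_ratio: float = 1.0,
    histories: Sequence[ChoiceHistory] | None = None,
    max_history_len: int = 3,
    **kernel_opts,
) -> pd.DataFrame:
    """Focal response P(next = A | history) across the noise grid.

    ``p_choose_A`` is the per-decision response probability (history fixed,
    focal utility from the prior); ``p_choose_A_joint`` is the exact
    conditional under the generative joint, for comparison.
    """
    if histories is None:
        histories = default_histories(max_history_len)
    rows = []
    for eps in sorted(eps_values):
        params = ModelParams(max(len(h) for h in histories) + 1, rho, eps, eta_ratio * eps)
        table = ThresholdTable(params, **kernel_opts)
        for h in sorted(histories, key=lambda h: (len(h), str(h))):
            rows.append({
                "rho": rho, "eps": eps, "eta": params.eta,
                "history": str(h),
                "p_choose_A": focal_response_probability(h, params, table),
                "p_choose_A_joint": conditional_choice_probability(h, params, table),
            })
    return pd.DataFrame(rows)


def conflict_sweep(
    rho_values: Iterable[float],
    eps_values: Iterable[float],
    eta_ratios: Iterable[float] = (1.0, 0.5),
    history: str = "BBA",
    **kernel_opts,
) -> pd.DataFrame:
    """The recency-vs-majority conflict: P(A | BBA) over a (rho, eps) grid.

    The history holds a majority for B but a most recent choice of A; the
    RSW column lets the grid collapse onto a single curve.
    """
    h = ChoiceHistory(history)
    rows = []
    for rho in sorted(rho_values):
        for eps in sorted(eps_values):
            thresholds = None
            for ratio in sorted(eta_ratios):
                params = ModelParams(len(h) + 1, rho, eps, ratio * eps)
                if thresholds is None:  # thresholds depend on eps only
                    thresholds = ThresholdTable(params, **kernel_opts)
                rows.append({
                    "rho": rho, "eps": eps, "eta_ratio": ratio,
                    "history": str(h),
                    "p_choose_A": focal_response_probability(h, params, thresholds),
                    "rsw": rsw(rho, eps),
                })
    return pd.DataFrame(rows)


def consensus_sweep(
    rho_values: Iterable[float],
    eps_values: Iterable[float],
    eta_ratios: Iterable[float] = (1.0, 0.5),
    n_agents: int = 8,
    include_distribution: bool = False,
    method: str = "joint",
    **kernel_opts,
) -> pd.DataFrame:
    """Expected consensus score of an N-agent group over a (rho, eps) grid."""
    rows = []
    for rho in sorted(rho_values):
        for eps in sorted(eps_values):
            thresholds = None
            for ratio in sorted(eta_ratios):
                params = ModelParams(n_agents, rho, eps, ratio * eps)
                if thresholds is None:
                    from .inference import build_threshold_table

                    thresholds = build_threshold_table(n_agents, params, **kernel_opts)
                dist = outcome_distribution(params, thresholds, method=method)
                row = {
                    "rho": rho, "eps": eps, "eta_ratio": ratio,
                    "expected_consensus": dist.expected_consensus(),
                    "rsw": rsw(rho, eps),
                }
                if include_distribution:
                    for k in range(n_agents + 1):
                        row[f"p_nA_{k}"] = dist.probability(k)
                rows.append(row)
    return pd.DataFrame(rows)


def subtype_sweep(
    spec: SubtypeSpec,
    eps_values: Iterable[float],
    eta_ratio: float = 1.0,
    histories: Sequence[ChoiceHistory] | None = None,
    focal_types: Sequence[str] = (ALPHA, BETA),
    max_history_len: int = 3,
    **kernel_opts,
) -> pd.DataFrame:
    """Type-conditional choice probabilities for a cryptic-subtype population."""
    if histories is None:
        histories = default_histories(max_history_len)
    rows = []
    for eps in sorted(eps_values):
        params = ModelParams(max(len(h) for h in histories) + 1, spec.rho_high, eps, eta_ratio * eps)
        table = SubtypeThresholdTable(spec, params, **kernel_opts)
        for focal in focal_types:
            for h in sorted(histories, key=lambda h: (len(h), str(h))):
                rows.append({
                    "gamma": spec.gamma, "rho_high": spec.rho_high,
                    "rho_low": spec.rho_low, "focal_type": focal,
                    "eps": eps, "eta": params.eta, "history": str(h),
                    "p_choose_A": focal_response_probability_subtype(
                        h, focal, spec, params, table),
                })
    return pd.DataFrame(rows)


def simulation_check(
    rho: float,
    eps: float,
    eta_ratio: float = 1.0,
    n_agents: int = 4,
    histories: Sequence[ChoiceHistory] | None = None,
    n_reps: int = 100_000,
    seed: int = 0,
    **kernel_opts,
) -> pd.DataFrame:
    """Exact-vs-Monte-Carlo table with z-scores, one row per history."""
    if histories is None:
        histories = default_histories(n_agents - 1)
    params = ModelParams(n_agents, rho, eps, eta_ratio * eps)
    table = ThresholdTable(params, **kernel_opts)
    run = simulate_group(params, table, n_reps=n_reps, seed=seed)
    rows = []
    for h in sorted(histories, key=lambda h: (len(h), str(h))):
        exact = conditional_choice_probability(h, params, table)
        try:
            emp, se = run.conditional_frequency(h)
        except ValueError:
            emp, se = np.nan, np.nan
        rows.append({
            "rho": rho, "eps": eps, "eta_ratio": eta_ratio, "history": str(h),
            "exact": exact, "estimate": emp, "stderr": se,
            "z": (emp - exact) / se if se and np.isfinite(se) and se > 0 else np.nan,
            "n_reps": n_reps, "seed": seed,
        })
    return pd.DataFrame(rows)
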