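"""Parameter containers and covariance structures for the correlated-utility model.

Each agent k holds a utility difference ``U_k`` between two options A and B,
standard normal a priori, built as a unit-norm weighted sum of shared
environmental factors.  The dot product of two agents' weight vectors is the
preference correlation ``rho``; private estimates ``Uhat_k = U_k + noise`` carry
sensory noise of scale ``eps`` (the level agents are habituated to) or ``eta``
(the level actually governing observations).  Choices are encoded A = +1,
B = -1 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

__all__ = [
    "ALPHA",
    "BETA",
    "ModelParams",
    "SubtypeSpec",
    "ChoiceHistory",
    "FactorLevelSpec",
    "type_sequences",
    "utility_correlation_matrix",
    "joint_covariance",
    "joint_covariance_from_corr",
]

#: Labels for the two cryptic preference types.
ALPHA = "alpha"
BETA = "beta"

_PSD_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Homogeneous-population parameters.

    Parameters
    ----------
    n_agents : int
        Group size N.
    rho : float
        Pairwise correlation between any two agents' utility functions.
        Must keep the N x N correlation matrix positive semidefinite, i.e.
        ``rho >= -1/(N-1)`` for N >= 2 (negative values are only possible
        in pairs or very small groups).
    eps : float
        Habitual environmental noise level (noise-to-signal ratio the
        agents' decision rule is calibrated to).  Strictly positive.
    eta : float, optional
        Experimental noise level actually governing private estimates when
        the group is observed.  Defaults to ``eps`` (natural conditions);
        ``eta < eps`` models low-noise laboratory conditions.
    """

    n_agents: int
    rho: float
    eps: float
    eta: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.eta is None:
            object.__setattr__(self, "eta", self.eps)
        if self.n_agents < 1:
            raise ValueError("n_agents must be a positive integer")
        if not self.eps > 0:
            raise ValueError("eps must be strictly positive")
        if not self.eta > 0:
            raise ValueError("eta must be strictly positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.n_agents >= 2:
            bound = -1.0 / (self.n_agents - 1)
            if self.rho < bound - _PSD_TOL:
                raise ValueError(
                    f"rho={self.rho} makes the {self.n_agents}x{self.n_agents} "
                    f"correlation matrix indefinite; need rho >= {bound:.6g}"
                )

    def with_eta(self, eta: float) -> "ModelParams":
        return ModelParams(self.n_agents, self.rho, self.eps, eta)


@dataclass(frozen=True)
class SubtypeSpec:
    """Two cryptic preference types, alpha and beta.

    Agents of the same type have utility correlation ``rho_high``; agents of
    different types have ``rho_low``.  ``gamma`` is the population fraction of
    type alpha.  Types are cryptic: observable only through choices, so every
    agent marginalises over the putative types of earlier deciders weighted by
    ``gamma**n_alpha * (1-gamma)**n_beta``.
    """

    gamma: float
    rho_high: float
    rho_low: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        for name in ("rho_high", "rho_low"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")

    def corr(self, type_a: str, type_b: str) -> float:
        """Pairwise utility correlation for a pair of (possibly equal) types."""
        return self.rho_high if type_a == type_b else self.rho_low


class ChoiceHistory:
    """An ordered sequence of binary decisions over {A, B}.

    Stored chronologically: ``ChoiceHistory("AAB")`` means the most recent
    observed choice was B, preceded by two choices of A.  Internally encoded
    as signs with A = +1, B = -1.
    """

    __slots__ = ("_signs",)

    def __init__(self, choices: Union[str, Iterable[int], "ChoiceHistory"] = ()):
        if isinstance(choices, ChoiceHistory):
            signs = choices._signs
        elif isinstance(choices, str):
            bad = set(choices.upper()) - {"A", "B"}
            if bad:
                raise ValueError(f"invalid choice labels {sorted(bad)}; use 'A'/'B'")
            signs = tuple(1 if c == "A" else -1 for c in choices.upper())
        else:
            signs = tuple(int(c) for c in choices)
            if any(c not in (-1, 1) for c in signs):
                raise ValueError("sign-encoded choices must be +1 (A) or -1 (B)")
        self._signs = signs

    @property
    def signs(self) -> tuple[int, ...]:
        return self._signs

    def mirror(self) -> "ChoiceHistory":
        """Swap A and B throughout."""
        return ChoiceHistory(tuple(-c for c in self._signs))

    def prefixes(self) -> Iterator["ChoiceHistory"]:
        """All proper prefixes, shortest first (including the empty history)."""
        for m in range(len(self._signs)):
            yield ChoiceHistory(self._signs[:m])

    def extended(self, choice: Union[str, int]) -> "ChoiceHistory":
        sign = choice if isinstance(choice, int) else (1 if choice.upper() == "A" else -1)
        return ChoiceHistory(self._signs + (sign,))

    def __len__(self) -> int:
        return len(self._signs)

    def __iter__(self):
        return iter(self._signs)

    def __getitem__(self, i):
        return self._signs[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, ChoiceHistory) and self._signs == other._signs

    def __hash__(self) -> int:
        return hash(self._signs)

    def __str__(self) -> str:
        return "".join("A" if c > 0 else "B" for c in self._signs) or "-"

    def __repr__(self) -> str:
        return f"ChoiceHistory({str(self)!r})"


def as_history(history: Union[str, Sequence[int], ChoiceHistory]) -> ChoiceHistory:
    return history if isinstance(history, ChoiceHistory) else ChoiceHistory(history)


def all_histories(length: int) -> list[ChoiceHistory]:
    """All 2**length choice histories of the given length, lexicographic (A first)."""
    out = [ChoiceHistory()]
    for _ in range(length):
        out = [h.extended(c) for h in out for c in (1, -1)]
    return out


def type_sequences(length: int, gamma: float) -> Iterator[tuple[tuple[str, ...], float]]:
    """Putative type assignments for ``length`` previous deciders.

    Yields ``(types, weight)`` with prior weight gamma**n_alpha *
    (1-gamma)**n_beta; assignments with zero weight are skipped.
    """
    if length == 0:
        yield (), 1.0
        return
    stack: list[tuple[tuple[str, ...], float]] = [((), 1.0)]
    for _ in range(length):
        nxt = []
        for types, w in stack:
            if gamma > 0.0:
                nxt.append((types + (ALPHA,), w * gamma))
            if gamma < 1.0:
                nxt.append((types + (BETA,), w * (1.0 - gamma)))
        stack = nxt
    yield from stack


@dataclass(frozen=True)
class FactorLevelSpec:
    """Explicit factor-level construction of the utility model.

    Utilities arise as ``U_k = sum_i alpha[i, k] * x_i`` with unit-norm weight
    vectors whose pairwise dot products equal the target correlations, and
    private estimates add independent per-factor noise residuals.  Used by the
    simulator's first-principles covariance check.
    """

    n_factors: int
    weight_vectors: np.ndarray = field(repr=False)  # (n_factors, n_agents)

    def __post_init__(self) -> None:
        W = np.asarray(self.weight_vectors, dtype=float)
        if W.ndim != 2 or W.shape[0] != self.n_factors:
            raise ValueError("weight_vectors must have shape (n_factors, n_agents)")
        norms = np.sum(W**2, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("each weight vector must have unit norm")
        object.__setattr__(self, "weight_vectors", W)

    @property
    def n_agents(self) -> int:
        return self.weight_vectors.shape[1]

    def implied_correlation(self) -> np.ndarray:
        return self.weight_vectors.T @ self.weight_vectors

    @classmethod
    def homogeneous(cls, n_agents: int, rho: float, n_factors: int) -> "FactorLevelSpec":
        """Weight vectors ``sqrt(rho) a_0 + sqrt(1-rho) a_k`` with orthonormal a_j.

        Requires ``rho >= 0`` (a shared component cannot produce negative
        correlation) and ``n_factors >= n_agents + 1``.
        """
        if not 0.0 <= rho <= 1.0:
            raise ValueError("homogeneous factor construction needs rho in [0, 1]")
        if n_factors < n_agents + 1:
            raise ValueError("need n_factors >= n_agents + 1 orthonormal directions")
        basis = np.eye(n_factors)[:, : n_agents + 1]
        W = np.sqrt(rho) * basis[:, [0]] + np.sqrt(1.0 - rho) * basis[:, 1:]
        return cls(n_factors=n_factors, weight_vectors=W)

    @classmethod
    def from_correlation(cls, corr: np.ndarray, n_factors: int) -> "FactorLevelSpec":
        """Weight vectors realising an arbitrary PSD target correlation matrix."""
        corr = np.asarray(corr, dtype=float)
        n = corr.shape[0]
        if n_factors < n:
            raise ValueError("need n_factors >= n_agents")
        w, V = np.linalg.eigh(corr)
        if w.min() < -1e-8:
            raise ValueError("target correlation matrix is not PSD")
        A = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))  # (n, n), rows are agents
        W = np.zeros((n_factors, n))
        W[:n, :] = A.T
        return cls(n_factors=n_factors, weight_vectors=W)


def _check_psd(corr: np.ndarray, context: str) -> np.ndarray:
    w = np.linalg.eigvalsh(corr)
    if w.min() < -_PSD_TOL * max(1.0, abs(w.max())):
        raise ValueError(
            f"{context}: correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g})"
        )
    return corr


def utility_correlation_matrix(
    params: Union[ModelParams, SubtypeSpec],
    types: Sequence[str] | None = None,
) -> np.ndarray:
    """Prior correlation matrix of the utilities ``(U_1, ..., U_N)``.

    For :class:`ModelParams` the matrix has unit diagonal and constant
    off-diagonal ``rho``.  For :class:`SubtypeSpec` a concrete type assignment
    must be supplied; off-diagonal entries are ``rho_high`` for same-type
    pairs and ``rho_low`` otherwise.
    """
    if isinstance(params, SubtypeSpec):
        if types is None:
            raise ValueError("a type assignment is required with SubtypeSpec")
        labels = list(types)
        n = len(labels)
        corr = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                corr[i, j] = 1.0 if i == j else params.corr(labels[i], labels[j])
        return _check_psd(corr, f"types={labels}")
    if types is not None:
        raise ValueError("type assignment only applies to SubtypeSpec")
    n = params.n_agents
    corr = np.full((n, n), params.rho)
    np.fill_diagonal(corr, 1.0)
    return _check_psd(corr, f"rho={params.rho}, N={n}")


def joint_covariance_from_corr(corr: np.ndarray, noise: float) -> np.ndarray:
    """Joint covariance of ``(U_1..U_N, Uhat_1..Uhat_N)`` given the U-block.

    Private estimates are ``Uhat_k = U_k + noise * z_k`` with independent
    standard-normal ``z_k``, so cov(Uhat_k, U_l) = cov(U_k, U_l) and
    cov(Uhat_k, Uhat_l) = cov(U_k, U_l) + noise**2 * delta_kl.
    """
    if not noise > 0:
        raise ValueError("noise level must be strictly positive")
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    out = np.empty((2 * n, 2 * n))
    out[:n, :n] = corr
    out[:n, n:] = corr
    out[n:, :n] = corr
    out[n:, n:] = corr + noise**2 * np.eye(n)
    return out


def joint_covariance(
    params: Union[ModelParams, SubtypeSpec],
    noise: float,
    types: Sequence[str] | None = None,
) -> np.ndarray:
    """2N x 2N joint covariance over ``(U_1..U_N, Uhat_1..Uhat_N)``.

    Pass ``noise=eps`` for the agents' internal model, ``noise=eta`` for the
    observer's generative model.
    """
    return joint_covariance_from_corr(utility_correlation_matrix(params, types), noise)
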