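# Methods

This note documents the model implemented by `ratdecide`, the numerical
choices behind the exact engine, what the Monte-Carlo simulator does and does
not emulate, and the design decisions taken where more than one reasonable
construction exists.

## Model

### Utilities and private information

A binary choice between options A and B is characterised by a vector of
independent environmental factor differences `x_1..x_n`, standardised to mean
zero and unit variance. Agent *k*'s utility difference is a weighted sum
`U_k = sum_i alpha_ik x_i` with a unit-norm weight vector (`sum_i alpha_ik^2
= 1`); the utility scale is fixed to one rather than exposed as a parameter,
since only ratios of utility to noise are identifiable. In the
many-factor (or Gaussian-factor) limit each `U_k` is standard normal and any
two agents' utilities have correlation `rho_kl = alpha_k . alpha_l`. The
implementation commits to this Gaussian limit; finite-factor deviations from
normality are not modelled, but the factor-level construction itself is kept
(as `FactorLevelSpec` plus `simulate_factor_level`) so the covariance
structure can be re-derived from first principles in tests rather than
trusted.

In an *undifferentiated* population every pair has the same alignment `rho`.
The N x N correlation matrix `(1-rho) I + rho J` requires `rho >= -1/(N-1)`;
mildly opposed preferences are therefore only representable in pairs and
very small groups, and `ModelParams` enforces the bound at construction.

Private estimates add factor-level noise residuals, independent across
agents and factors, with noise-to-signal ratio `eps`:
`Uhat_k = U_k + sum_i alpha_ik nu_ik`, giving `Uhat_k | U_k ~ N(U_k, eps^2)`
and the joint covariance listed in the README. All conditional laws used
anywhere in the package (agent-side likelihoods, observer-side generative
distributions) are derived mechanically from that joint by Gaussian
conditioning — no conditional covariance is hand-entered. In particular the
conditional variance of an earlier agent's estimate given the focal agent's
utility is `1 + eps^2 - rho^2` (not `1 + eps^2`), and the conditional
covariance between two earlier estimates is `rho - rho^2`; both fall out of
the joint and are validated against rejection sampling.

### Sequential rational choice

Agents decide in a fixed, known order. Agent 1 chooses A iff `Uhat_1 > 0`.
Agent *k* observing choices `C_1..C_{k-1}` holds the posterior

```
p(U_k | Uhat_k, C_1..C_{k-1})
    ∝ phi(U_k) phi((Uhat_k - U_k)/eps) P(C_1..C_{k-1} | U_k)
```

where the history likelihood is the probability that each earlier estimate
fell on the side of that agent's own critical value matching its choice:
an (k-1)-dimensional rectangle probability under the conditional law of
`(Uhat_1..Uhat_{k-1})` given `U_k`, with coordinate *j* bounded below by
`Uhat*_j` if `C_j = A` and above if `C_j = B`. The critical value `Uhat*_k`
is the unique root in `Uhat_k` of the posterior mean (the posterior mean is
strictly increasing in the private estimate, which the test suite checks on
a grid). Since each earlier threshold is itself defined by the same
construction one level down, thresholds are computed recursively and
memoised per history. Swapping A and B everywhere negates every threshold
exactly, so only histories beginning with A are solved; mirrors are negated,
which enforces the antisymmetry identically rather than approximately.

Ties `Uhat = Uhat*` resolve to B (choice A requires strictly exceeding the
threshold). The event has probability zero; fixing it keeps the simulator
bitwise deterministic.

### Observation and the two next-choice quantities

An observer records choices under an experimental noise level `eta`, which
may differ from the habitual `eps` the agents' thresholds are calibrated to
("natural conditions" means `eta = eps` exactly; the laboratory condition is
parameterised by the ratio `eta/eps`, with 1/2 as the conventional low-noise
setting). Sequence probabilities are rectangle probabilities of
`(Uhat_1..Uhat_m)` under the eta-generative joint with the eps-calibrated
thresholds as bounds.

The package deliberately distinguishes two next-choice quantities:

* **Exact conditional** `P(C_next = A | C_1..C_m)`, the ratio of two
  sequence probabilities (computed as `P(h+A) / (P(h+A) + P(h+B))`, which is
  identical in exact arithmetic and exactly self-consistent under
  quadrature). Because utilities are correlated, conditioning on the history
  also shifts the focal agent's own estimate: at `rho = 0.5`,
  `eps = eta = 0.05` the exact conditional after B,B,A is 0.403 — the focal
  agent's utility itself is probably B-ish given two B choices. This is the
  quantity estimated by filtering simulated (or recorded) sequences, and it
  is what the Monte-Carlo oracle checks.
* **Response probability** `Phi(-Uhat*_h / sqrt(1 + eta^2))`: the response
  curve of a focal agent whose utility is drawn fresh from the prior, facing
  a fixed observed history. The history enters only through the threshold,
  so successive decisions are treated as independent given the threshold
  cascade. This is the quantity shown in the figure-style sweeps: it returns
  to exactly 0.5 whenever the threshold vanishes (hence in the low-noise
  limit), its `P = 0.5` contour is exactly invariant to `eta`, and lowering
  `eta` at fixed `eps` sharpens it monotonically.

Both are exposed; sweep tables carry the response probability in
`p_choose_A` (with the exact conditional alongside in `conditional_sweep`).
The distinction matters: the two differ most exactly where private
information is strong, and conflating them changes qualitative conclusions
about low-noise behaviour.

A note on the identical-preferences limit: at `rho = 1` the relative social
weighting is 1 at every noise level, so the *balance* of social versus
private information is noise-invariant. The choice probabilities themselves
are not exactly noise-invariant under either quantity above: with a proper
standard-normal utility prior, prior shrinkage breaks scale invariance
(e.g. the response after one A is 0.649, 0.724, 0.768 at `eps` = 0.5, 1, 2).
Exact invariance would require a scale-free (improper) prior, which the
model excludes by fixing the prior variance to one.

### Group outcomes

For a group of N agents the distribution over the final count `n_A` is
computed by enumerating all 2^N ordered sequences (guarded at N <= 10). The
default method sums exact sequence probabilities; since all 2^N leaf boxes
share one N x N covariance they are evaluated in a single batched kernel
call. A `chain` method multiplies response probabilities down each branch
instead (decisions independent given the threshold cascade) — the cheap
pipeline matching the figure-style response curves. The two coincide exactly
at `rho = 0`, where both reduce to Binomial(N, 1/2); the expected consensus
`E|n_A - n_B|/N` is then 35/128 for N = 8, used as an exact anchor in the
tests.

### Cryptic subtypes

Two types alpha/beta with within-type correlation `rho_high`, between-type
`rho_low`, and alpha-fraction `gamma`. Types are cryptic: each agent knows
its *own* type but observes only choices, so the history likelihood is a
mixture over putative type sequences `s` of earlier deciders weighted by
`gamma^n_alpha (1-gamma)^n_beta`, each term a rectangle probability under
that sequence's covariance, with earlier agents bounded at their *own-type*
thresholds. Because every agent marginalises earlier types the same way, one
threshold per (own type, history) pair suffices, which keeps the recursion
polynomial in practice (the mixture itself is 2^m per history of length m).
Two modelling commitments are made where the construction is genuinely open:
the focal agent's prior over others' types is (gamma, 1-gamma) regardless of
its own type (types are population frequencies, not kin structure), and only
two types are supported. `rho_low < rho_high` is not enforced — any
combination passing the positive-semidefiniteness check of the implied
correlation matrices is accepted.

## Numerics

* **Rectangle probabilities** use the Genz separation-of-variables transform
  on a scrambled Sobol point set (default 8192 points, fixed internal
  scramble seed), vectorised over a batch of integration boxes sharing one
  covariance — the hot path evaluates all Gauss-Hermite nodes of a posterior
  integrand in one call. Points are paired antithetically (`w`, `1-w`),
  which makes the kernel exactly symmetric under reflection of the box
  through the origin: mirrored histories get equal probabilities, mirror
  sums equal 1, and exhaustive partitions sum to 1 at float precision.
  Accuracy against an independent implementation (scipy's randomised-QMC
  MVN CDF) is ~3e-8 at dimensions 2–8, comfortably inside the 1e-6 contract;
  scipy's own CDF is not used internally because it is nondeterministic
  run-to-run. Rank-deficient covariances (e.g. `rho = 1`) fall back to an
  eigendecomposition-verified Cholesky with a 1e-12 ridge.
* **Posterior means** integrate over the Gaussian envelope
  `N(uhat/(1+eps^2), eps^2/(1+eps^2))` of the no-social-information
  posterior with 64-node probabilists' Gauss-Hermite quadrature; the
  envelope times the bounded, smooth rectangle factor is exactly the
  integrand class Gauss-Hermite handles well. The standalone
  `expectation_over_gaussian` doubles nodes (96 up to 1024) until two
  successive estimates agree to 1e-9 relative.
* **Thresholds** are found with Brent's method at `xtol = 1e-8` after
  geometric bracket expansion from [-1, 1] (failure beyond ±50 raises,
  signalling a degenerate posterior). 1e-8 is far below the ~1e-6
  integration noise of the rectangle probabilities the thresholds feed into.
* **Degenerate inputs**: zero correlation short-circuits (the likelihood is
  constant in the focal utility, so thresholds are exactly 0); histories
  with vanishing probability (< 1e-12) raise rather than return a ratio of
  noise.

## The simulator

`simulate_group` draws `U ~ MVN(0, Sigma)` and `Uhat = U + eta z` with
independent standard-normal `z` — at the utility level the estimate
residuals are independent across agents, which reproduces the required
`Uhat` covariance given the `U` correlation — then applies the sequential
threshold rule replicate by replicate. One seeded generator per run; a fixed
seed reproduces choice sequences bitwise. `simulate_subtype_group`
additionally draws types i.i.d. Bernoulli(gamma) per seat and groups
replicates by type pattern so each pattern uses one covariance.
`simulate_factor_level` rebuilds the joint covariance from explicit weight
vectors over factors (shared direction `sqrt(rho) a_0` plus orthogonal
idiosyncratic directions in the homogeneous case; a Cholesky-style
construction for arbitrary targets) — a first-principles check that the
closed-form joint is the right one, not just internally consistent.

The simulator emulates exactly the generative model above: known decision
order, one decision per agent, homogeneous sensory noise, Gaussian factors.
It does not emulate features of real experiments — unknown or partial
observation order, choice revision, agent-specific noise, non-Gaussian
utilities — so agreement between engine and simulator certifies the
implementation, not the model's fit to any real group.

## Problem sizes and tolerances used in the shipped checks

Response curves and conditionals are exercised at N = 4 (histories up to
length 3, the standard figure setting); exhaustive outcome enumeration at
N = 6 in the worked example and N = 8 for the exact binomial anchor;
Monte-Carlo cross-checks use 1e5 replicates for choice frequencies (3
standard errors, with at least 95% of conditions within 3 SE across the
(rho, eps) grid) and 5e5–6e5 draws for rejection-sampling posterior means at
acceptance window ±0.05. The recency-majority transition scan brackets the
noise level in [0.1, 10] and refines to 1e-4.

## Known limitations

* Observer-side exhaustive enumeration is exponential in N (guarded at 10);
  rectangle probabilities are intended for dimension <= ~12.
* Exactly two cryptic types; the subtype mixture is exponential in history
  length (fine for the figure-scale histories it serves).
* No iterative choice revision: agents decide once, in order. Revision
  would generally raise consensus, so consensus surfaces are comparative
  statements, not point predictions for freely interacting groups.
* `eps` is common to all agents (homogeneous sensory sensitivity);
  preference heterogeneity enters only through `rho` or the two-type
  structure.
* Estimating `rho`, `eps`, `eta` from behavioural data is out of scope; the
  package predicts forward from parameters.
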