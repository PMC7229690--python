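"""Cryptic preference types: unanimity effects and minority leadership.

Two scenarios of a two-type population whose types are observable only
through behaviour: (1) two equally prevalent types with identical
within-type and zero between-type preference correlation, where unanimity
among previous deciders is qualitatively special; (2) a 90/10 split with
high within-type and low between-type alignment, where the majority type is
strongly social and the minority type largely ignores the crowd.
"""

from ratdecide import (
    ALPHA,
    BETA,
    ModelParams,
    SubtypeThresholdTable,
    SUBTYPE_PRESETS,
    focal_response_probability_subtype,
)

spec = SUBTYPE_PRESETS["equal_split"]
params = ModelParams(5, spec.rho_high, 0.3)
table = SubtypeThresholdTable(spec, params)
print("Scenario 1: gamma=0.5, rho_high=1, rho_low=0, low noise (eps = 0.3)")
print("history   P(A | history)")
for h in ("AAA", "AAB", "ABA", "BAA"):
    p = focal_response_probability_subtype(h, ALPHA, spec, params, table)
    print(f"{h:<8}  {p:7.4f}")
print("A unanimous run of A's implies the previous deciders likely share one")
print("type - possibly the focal agent's own - and is followed strongly; a")
print("single break returns the agent to its private information.")
print()

spec = SUBTYPE_PRESETS["majority_minority"]
params = ModelParams(5, spec.rho_high, 1.0)
table = SubtypeThresholdTable(spec, params)
print("Scenario 2: gamma=0.9, rho_high=0.9, rho_low=0.25, eps = 1")
print("history   majority-type P(A)  minority-type P(A)")
for h in ("A", "AA", "AAA", "AAB"):
    pa = focal_response_probability_subtype(h, ALPHA, spec, params, table)
    pb = focal_response_probability_subtype(h, BETA, spec, params, table)
    print(f"{h:<8}  {pa:16.4f}  {pb:16.4f}")
print("Majority-type agents treat the crowd as aligned and follow it; the")
print("minority type responds weakly, a rational basis for minority leadership.")
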