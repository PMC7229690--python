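"""Resolving a conflict between the majority and the most recent decision.

History BBA pits two early choices of B against a most recent choice of A.
Scanning the habitual noise level at strong preference alignment locates the
transition where following recency and following the majority are equally
likely, and reports the relative social weighting there.
"""

import numpy as np
from scipy.optimize import brentq

from ratdecide import ModelParams, ThresholdTable, focal_response_probability, rsw

RHO = 0.9


def p_recent(eps: float) -> float:
    params = ModelParams(4, RHO, eps)
    return focal_response_probability("BBA", params, ThresholdTable(params))


print(f"rho = {RHO}, natural conditions (eta = eps)")
print("eps     P(A|BBA)   RSW")
for eps in np.geomspace(0.1, 10, 7):
    print(f"{eps:5.2f}   {p_recent(eps):7.4f}  {rsw(RHO, eps):6.3f}")

eps_star = brentq(lambda e: p_recent(e) - 0.5, 0.1, 10.0, xtol=1e-4)
print()
print(f"Transition at eps* = {eps_star:.4f}, where RSW = {rsw(RHO, eps_star):.3f}:")
print("below it the agent sides with the majority (P < 0.5), above it the most")
print("recent decision wins (P > 0.5); at very low noise the response returns")
print("to exactly 0.5 because social information carries no weight at all.")
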