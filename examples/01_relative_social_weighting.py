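"""How strongly should a rational agent weight another's choice?

The relative social weighting RSW = rho*eps / sqrt(1 + eps^2 - rho^2)
compares the weight a rational second decider places on the first agent's
choice against the weight on its own private estimate, as a function of the
preference correlation rho and the habitual noise-to-signal ratio eps.
"""

from ratdecide import rsw

print("rho   eps    RSW")
for rho, eps in [(1.0, 0.1), (1.0, 5.0), (0.0, 1.0), (0.5, 0.05),
                 (0.5, 1.0), (0.5, 100.0), (0.9, 1.0), (-0.8, 1.0)]:
    print(f"{rho:4.1f}  {eps:6.2f}  {rsw(rho, eps):+.4f}")

print()
print("Identical preferences (rho=1) give full weight to social information at")
print("any noise level; uncorrelated preferences give none.  Between these, a")
print("noisy environment (eps >> 1) pushes the weight up towards rho itself,")
print("while reliable private information (eps << 1) silences social cues.")
print("Opposed preferences (rho < 0) make the other's choice actively repulsive.")
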