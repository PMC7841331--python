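"""Pharmacodynamic effect curves: Emax versus sigmoid Hill.

Evaluates s(c) at a few concentrations for Hill exponents 1 and 3 and shows
the defining identity s(EC50) = E0 + Emax/2.
"""

from chemocontrol import effect
from chemocontrol.model import PDParams

for hill_k in (1, 3):
    pd = PDParams(e0=0.0, emax=100.0, ec50=15.0, hill_k=hill_k)
    vals = {c: effect(c, pd, "sigmoid") for c in (0.0, 5.0, 15.0, 30.0, 150.0)}
    row = "  ".join(f"s({c:g})={v:.2f}" for c, v in vals.items())
    print(f"hill_k={hill_k}:  {row}")
print("At c = EC50 = 15 both models give exactly the half-maximal effect 50;")
print("a larger Hill exponent steepens the curve around EC50.")
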