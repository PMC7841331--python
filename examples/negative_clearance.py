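"""Sign of the dose-dependent clearance flips the concentration regime.

With k2 > 0 the concentration saturates; with k2 < 0 high doses slow
elimination, so the curve keeps climbing (slight dips persist at dose
troughs, where u(t) = 0 and c decays at rate k1).
"""

from chemocontrol import reference_setup, set_param, simulate

params, schedule, _ = reference_setup()
pos = simulate(params, schedule, t_end=500.0)
neg = simulate(set_param(params, "k2", -0.0004), schedule, t_end=500.0)

print(f"k2 = +0.0004: c(500) = {pos.c_values[-1]:.3f}  (plateau regime)")
print(f"k2 = -0.0004: c(500) = {neg.c_values[-1]:.3f}  (growing regime)")
print(f"excess concentration at t=500: {neg.c_values[-1] - pos.c_values[-1]:.3f}")
print("Once concentration has built up, negative k2 lets smaller doses sustain")
print("a high drug level: elimination weakens as dosing continues.")
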