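"""Kalman rank tests: textbook systems and the linearized PK-PD model.

The bilinear model itself is not linear time-invariant; the package
linearizes it about a reference operating point so the rank condition
rank [B | AB | ... | A^{n-1}B] = n can be applied as a local check.
"""

from chemocontrol import LinearSystem, is_controllable, linearize, reference_setup, set_param

double_integrator = LinearSystem([[0, 1], [0, 0]], [[0], [1]])
res = is_controllable(double_integrator)
print(f"double integrator: rank {res.rank}/{res.n_states} -> controllable={res.controllable}")

params, _, _ = reference_setup()
sys = linearize(params, c_ref=1.0, n_ref=[1.0], u_ref=10.0)
res = is_controllable(sys)
print(f"linearized PK-PD (B=0.001): rank {res.rank}/{res.n_states} -> "
      f"controllable={res.controllable}")

no_coupling = set_param(params, "B", 0.0)
res = is_controllable(linearize(no_coupling, c_ref=1.0, n_ref=[1.0], u_ref=10.0))
print(f"linearized, drug decoupled (B=0): rank {res.rank}/{res.n_states} -> "
      f"controllable={res.controllable}")
print("Without the PD coupling the dose can steer the concentration but never")
print("the tumor compartment, and the rank drops below the state dimension.")
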