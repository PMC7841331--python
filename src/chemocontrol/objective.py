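"""L1-type objective functional for chemotherapy scheduling.

J = p.N(T) + int_0^T (q.N(t) + b.u(t)) dt

combines the terminal tumor burden, the running tumor burden (penalizing
intermediate excursions) and the cumulative dose, which stands in for
toxicity to healthy tissue.  The package evaluates J on trajectories; it
does not synthesize optimal controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import simpson, trapezoid

from .model import DoseSchedule, ModelParams, set_param
from .simulate import Trajectory, simulate

__all__ = [
    "ObjectiveWeights",
    "evaluate_objective",
    "terminal_cost",
    "running_cost_integral",
    "sweep_objective",
]


@dataclass(frozen=True)
class ObjectiveWeights:
    """Non-negative weights (p, q, b) and the therapy horizon T.

    ``p`` weights the terminal cell counts, ``q`` the running cell counts
    and ``b`` the dose; for killing agents ``b`` is positive. Defaults are
    the reference study's unit weights over a 500 time-unit horizon.
    """

    p: NDArray[np.float64] = field(default_factory=lambda: np.ones(1))
    q: NDArray[np.float64] = field(default_factory=lambda: np.ones(1))
    b: float = 1.0
    t_horizon: float = 500.0

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p, float))
        q = np.atleast_1d(np.asarray(self.q, float))
        for name, v in (("p", p), ("q", q), ("b", np.atleast_1d(self.b))):
            if np.any(v < 0):
                raise ValueError(f"{name} must be entry-wise non-negative")
        if not (p.any() or q.any() or self.b):
            raise ValueError("weights must not all be zero")
        if self.t_horizon <= 0:
            raise ValueError("t_horizon must be positive")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "b", float(self.b))


def _restrict(traj: Trajectory, T: float):
    """Times/N/u restricted to [0, T], interpolating the endpoint onto T."""
    if traj.times[-1] < T - 1e-9:
        raise ValueError(
            f"trajectory ends at t={traj.times[-1]:g}, before the horizon T={T:g}"
        )
    mask = traj.times <= T + 1e-12
    t = traj.times[mask]
    n = traj.n_values[mask]
    u = traj.u_values[mask]
    if t[-1] < T - 1e-12:
        n_T = np.array([np.interp(T, traj.times, traj.n_values[:, i])
                        for i in range(traj.n_compartments)])
        u_T = np.interp(T, traj.times, traj.u_values)
        t = np.append(t, T)
        n = np.vstack([n, n_T])
        u = np.append(u, u_T)
    return t, n, u


def terminal_cost(traj: Trajectory, w: ObjectiveWeights) -> float:
    """p.N(T)."""
    _, n, _ = _restrict(traj, w.t_horizon)
    return float(w.p @ n[-1])


def running_cost_integral(
    traj: Trajectory, w: ObjectiveWeights, rule: str = "trapezoid"
) -> float:
    """int_0^T (q.N + b.u) dt by composite trapezoid (default) or Simpson."""
    t, n, u = _restrict(traj, w.t_horizon)
    integrand = n @ w.q + w.b * u
    if rule == "trapezoid":
        return float(trapezoid(integrand, t))
    if rule == "simpson":
        return float(simpson(integrand, x=t))
    raise ValueError(f"unknown quadrature rule {rule!r}")


def evaluate_objective(
    traj: Trajectory, w: ObjectiveWeights, rule: str = "trapezoid"
) -> float:
    """J = terminal cost + running-cost integral over [0, T]."""
    return terminal_cost(traj, w) + running_cost_integral(traj, w, rule=rule)


def sweep_objective(
    params: ModelParams,
    schedule: DoseSchedule,
    w: ObjectiveWeights,
    sweep_param: str,
    values: Sequence[float] | ArrayLike,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Re-simulate and evaluate J for each value of one named parameter.

    Returns a DataFrame with columns ``param_value`` and ``J``, rows in the
    order of the input grid.  Unknown parameter names raise a KeyError
    listing the valid names.
    """
    values = np.atleast_1d(np.asarray(values, float))
    if values.size == 0:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for v in values:
        p_v = set_param(params, sweep_param, v)
        traj = simulate(p_v, schedule, t_end=w.t_horizon, rtol=rtol, atol=atol)
        rows.append((float(v), evaluate_objective(traj, w)))
    return pd.DataFrame(rows, columns=["param_value", "J"])
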