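"""Numerical integration of the coupled tumor/PK dynamics.

The coupled system

    dN/dt = [A + s(c) B] N,        N(0) = N0
    dc/dt = -(k1 + k2 u(t)) c + h u(t),   c(0) = 0

is integrated with an adaptive explicit Runge-Kutta 4(5) scheme; the system
is non-stiff at the reference parameters.  Trajectory rows live on a uniform
reporting grid (default 1 time-unit spacing), not on solver steps.  The
concentration equation is autonomous from N and can be integrated alone
(:func:`simulate_concentration`), which the sensitivity machinery exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import quad_vec, solve_ivp
from scipy.linalg import expm

from .model import DoseSchedule, ModelParams, effect, pk_rhs, tumor_rhs

__all__ = [
    "Trajectory",
    "SimulationDivergedError",
    "simulate",
    "simulate_concentration",
    "closed_form_lti",
]

#: States exceeding this magnitude abort the integration with a diagnostic.
BLOWUP_LIMIT = 1e12


class SimulationDivergedError(RuntimeError):
    """Raised when a state variable exceeds the blow-up guard."""


@dataclass(frozen=True)
class Trajectory:
    """Time histories of the simulated system on the reporting grid.

    Attributes
    ----------
    times : (T,) strictly increasing time grid
    n_values : (T, n) per-compartment cell counts
    c_values : (T,) drug concentration
    u_values : (T,) administered dose
    running_cost : (T,) objective integrand q.N(t) + b.u(t) (unit weights
        unless others were passed to :func:`simulate`)
    """

    times: NDArray[np.float64]
    n_values: NDArray[np.float64]
    c_values: NDArray[np.float64]
    u_values: NDArray[np.float64]
    running_cost: NDArray[np.float64]

    def __post_init__(self) -> None:
        T = self.times.shape[0]
        if not (
            self.n_values.shape[0] == T
            and self.c_values.shape == (T,)
            and self.u_values.shape == (T,)
            and self.running_cost.shape == (T,)
        ):
            raise ValueError("trajectory arrays must share their time dimension")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_compartments(self) -> int:
        return self.n_values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times, "c": self.c_values, "u": self.u_values,
                "running_cost": self.running_cost}
        for i in range(self.n_compartments):
            cols[f"N_{i + 1}"] = self.n_values[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        """Write `time,c,u,running_cost,N_1..N_n` with deterministic order."""
        self.to_frame().to_csv(path, index=False)


def _reporting_grid(t_end: float, n_steps: Optional[int]) -> NDArray[np.float64]:
    if n_steps is None:
        n_steps = max(int(round(t_end)) + 1, 2)
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    return np.linspace(0.0, t_end, n_steps)


def _guarded_solve(rhs, t_end, y0, t_eval, rtol, atol, state_names):
    guard = lambda t, y: BLOWUP_LIMIT - np.max(np.abs(y))  # noqa: E731
    guard.terminal = True
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="RK45", t_eval=t_eval,
        rtol=rtol, atol=atol, events=guard,
    )
    if sol.status == 1:  # guard event fired
        y_last = sol.y_events[0][-1]
        worst = state_names[int(np.argmax(np.abs(y_last)))]
        raise SimulationDivergedError(
            f"state {worst!r} exceeded {BLOWUP_LIMIT:g} at t={sol.t_events[0][-1]:.3g}"
        )
    if not sol.success:
        raise SimulationDivergedError(f"integrator failed: {sol.message}")
    return sol


def simulate(
    params: ModelParams,
    schedule: DoseSchedule,
    t_end: float = 500.0,
    n_steps: Optional[int] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    q_weights: Optional[ArrayLike] = None,
    b_weight: float = 1.0,
) -> Trajectory:
    """Integrate the coupled tumor/PK system with c(0)=0, N(0)=n0.

    ``q_weights`` and ``b_weight`` only parameterize the reported running-cost
    column (defaults: all ones); they do not affect the dynamics.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    times = _reporting_grid(t_end, n_steps)
    schedule.validate_nonnegative(times)

    n = params.tumor.n_compartments
    q = np.ones(n) if q_weights is None else np.asarray(q_weights, float)

    def rhs(t, y):
        n_vec, c = y[:n], max(y[n], 0.0)
        s = effect(c, params.pd, params.effect_model)
        u = schedule(t)
        return np.concatenate([tumor_rhs(n_vec, s, params.tumor), [pk_rhs(c, u, params.pk)]])

    names = [f"N_{i + 1}" for i in range(n)] + ["c"]
    y0 = np.concatenate([params.n0, [0.0]])
    sol = _guarded_solve(rhs, t_end, y0, times, rtol, atol, names)

    u_vals = np.atleast_1d(schedule(times)).astype(float)
    n_vals = sol.y[:n].T
    c_vals = sol.y[n]
    return Trajectory(
        times=times,
        n_values=n_vals,
        c_values=c_vals,
        u_values=u_vals,
        running_cost=n_vals @ q + b_weight * u_vals,
    )


def simulate_concentration(
    pk,
    schedule: DoseSchedule,
    t_end: float = 500.0,
    n_steps: Optional[int] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    c0: float = 0.0,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Integrate the concentration equation alone (it does not depend on N).

    Returns ``(times, c)`` on the reporting grid.  Useful whenever only the
    pharmacokinetic response is of interest, e.g. concentration envelopes, or
    to continue a run from a stored concentration ``c0`` (dosing-interruption
    studies).
    """
    times = _reporting_grid(t_end, n_steps)
    schedule.validate_nonnegative(times)
    rhs = lambda t, y: [pk_rhs(max(y[0], 0.0), schedule(t), pk)]  # noqa: E731
    sol = _guarded_solve(rhs, t_end, [c0], times, rtol, atol, ["c"])
    return times, sol.y[0]


def closed_form_lti(
    a_matrix: ArrayLike,
    b_matrix: ArrayLike,
    x0: ArrayLike,
    u: Callable[[float], ArrayLike],
    t: float,
) -> NDArray[np.float64]:
    """Exact LTI solution x(t) = e^{At}[x0 + int_0^t e^{-A tau} B u(tau) dtau].

    Evaluated with the matrix exponential and adaptive quadrature; serves as
    an independent oracle for linear specializations of the dynamics (e.g.
    the concentration equation when k2 = 0).
    """
    A = np.atleast_2d(np.asarray(a_matrix, float))
    B = np.atleast_2d(np.asarray(b_matrix, float))
    x0 = np.atleast_1d(np.asarray(x0, float))
    if t == 0:
        return x0.copy()

    def integrand(tau):
        return expm(-A * tau) @ (B @ np.atleast_1d(np.asarray(u(tau), float)))

    integral, _ = quad_vec(integrand, 0.0, t, epsabs=1e-12, epsrel=1e-10)
    return expm(A * t) @ (x0 + integral)
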