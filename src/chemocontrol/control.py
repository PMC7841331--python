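"""Linear time-invariant systems and the Kalman controllability test.

An LTI system dx/dt = A x + B u is controllable iff the Kalman matrix
E = [B | AB | A^2 B | ... | A^{n-1} B] has full row rank n.  The bilinear
tumor/PK model is not LTI; :func:`linearize` provides a local linearization
about a reference operating point so the rank test can be applied to it as
an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model import ModelParams, effect, effect_derivative

__all__ = [
    "LinearSystem",
    "ControllabilityResult",
    "controllability_matrix",
    "is_controllable",
    "linearize",
]


@dataclass(frozen=True)
class LinearSystem:
    """Constant matrices (A, B) and optional output maps (C, D).

    A is n x n, B is n x m; if present, C is p x n and D is p x m.
    """

    a_matrix: NDArray[np.float64]
    b_matrix: NDArray[np.float64]
    c_matrix: Optional[NDArray[np.float64]] = None
    d_matrix: Optional[NDArray[np.float64]] = None

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.a_matrix, float))
        B = np.atleast_2d(np.asarray(self.b_matrix, float))
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got {A.shape}")
        if B.shape[0] != A.shape[0]:
            raise ValueError(f"B has {B.shape[0]} rows, expected {A.shape[0]}")
        object.__setattr__(self, "a_matrix", A)
        object.__setattr__(self, "b_matrix", B)
        for name in ("c_matrix", "d_matrix"):
            M = getattr(self, name)
            if M is not None:
                M = np.atleast_2d(np.asarray(M, float))
                object.__setattr__(self, name, M)
        if self.c_matrix is not None and self.c_matrix.shape[1] != A.shape[0]:
            raise ValueError("C must have n columns")
        if self.d_matrix is not None:
            if self.c_matrix is None:
                raise ValueError("D requires C")
            if self.d_matrix.shape != (self.c_matrix.shape[0], B.shape[1]):
                raise ValueError("D must be p x m")

    @property
    def n_states(self) -> int:
        return self.a_matrix.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.b_matrix.shape[1]

    @classmethod
    def from_json_dict(cls, d: dict) -> "LinearSystem":
        return cls(
            a_matrix=np.asarray(d["a_matrix"], float),
            b_matrix=np.asarray(d["b_matrix"], float),
            c_matrix=None if d.get("c_matrix") is None else np.asarray(d["c_matrix"], float),
            d_matrix=None if d.get("d_matrix") is None else np.asarray(d["d_matrix"], float),
        )


@dataclass(frozen=True)
class ControllabilityResult:
    controllable: bool
    rank: int
    n_states: int

    def __bool__(self) -> bool:
        return self.controllable


def controllability_matrix(sys: LinearSystem) -> NDArray[np.float64]:
    """Kalman matrix [B | AB | ... | A^{n-1}B], shape n x (n*m)."""
    A, B = sys.a_matrix, sys.b_matrix
    blocks, current = [], B
    for _ in range(sys.n_states):
        blocks.append(current)
        current = A @ current
    return np.hstack(blocks)


def is_controllable(sys: LinearSystem, rank_tol: Optional[float] = None) -> ControllabilityResult:
    """Kalman rank test: controllable iff rank(E) == n.

    The numerical rank uses the standard singular-value convention
    max(dim) * eps * sigma_max unless ``rank_tol`` overrides it.
    """
    E = controllability_matrix(sys)
    rank = int(np.linalg.matrix_rank(E, tol=rank_tol))
    return ControllabilityResult(rank == sys.n_states, rank, sys.n_states)


def linearize(
    params: ModelParams,
    c_ref: float,
    n_ref: ArrayLike,
    u_ref: float = 0.0,
) -> LinearSystem:
    """Linearize the coupled tumor/PK dynamics about (N*, c*, u*).

    State order is (N_1..N_n, c), single input u.  The Jacobian blocks are

        d(dN/dt)/dN = A + s(c*) B       d(dN/dt)/dc = s'(c*) B N*
        d(dc/dt)/dc = -(k1 + k2 u*)     d(dc/dt)/du = h - k2 c*

    This is a package-added convenience: the rank test applies to the
    linearization only, as a local approximation of the bilinear model.
    """
    n = params.tumor.n_compartments
    n_ref = np.atleast_1d(np.asarray(n_ref, float))
    if n_ref.shape != (n,):
        raise ValueError(f"n_ref must have length {n}")
    s = effect(c_ref, params.pd, params.effect_model)
    ds = effect_derivative(c_ref, params.pd, params.effect_model)
    A_lin = np.zeros((n + 1, n + 1))
    A_lin[:n, :n] = params.tumor.a_matrix + s * params.tumor.b_matrix
    A_lin[:n, n] = ds * (params.tumor.b_matrix @ n_ref)
    A_lin[n, n] = -(params.pk.k1 + params.pk.k2 * u_ref)
    B_lin = np.zeros((n + 1, 1))
    B_lin[n, 0] = params.pk.h - params.pk.k2 * c_ref
    return LinearSystem(A_lin, B_lin)
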