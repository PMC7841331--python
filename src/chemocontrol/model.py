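"""Domain types and right-hand-side mathematics of the bilinear PK-PD model.

The model couples a multi-compartment tumor population ``dN/dt = [A + s(c)B]N``
to a first-order pharmacokinetic equation ``dc/dt = -(k1 + k2*u(t))*c + h*u(t)``
through a pharmacodynamic effect function ``s(c)`` (Emax or sigmoid Hill).
All quantities are in arbitrary units; the model is a qualitative testbed for
cell-cycle-specific chemotherapy scheduling, not a fitted clinical model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Union

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "PDParams",
    "PKParams",
    "TumorParams",
    "ModelParams",
    "DoseSchedule",
    "effect",
    "effect_derivative",
    "pk_rhs",
    "tumor_rhs",
    "set_param",
    "get_param",
    "PARAM_NAMES",
]


@dataclass(frozen=True)
class PDParams:
    """Pharmacodynamic effect-curve parameters.

    Parameters
    ----------
    e0 : float
        Baseline efficacy at zero concentration (effect units, >= 0).
    emax : float
        Maximum attainable efficacy above baseline (effect units, >= 0).
    ec50 : float
        Potency: concentration producing half-maximal effect (> 0).
    hill_k : int
        Hill exponent for the sigmoid model (integer >= 1); ``hill_k=1``
        recovers the Emax model exactly.
    """

    e0: float = 0.0
    emax: float = 100.0
    ec50: float = 15.0
    hill_k: int = 1

    def __post_init__(self) -> None:
        if self.e0 < 0:
            raise ValueError(f"e0 must be >= 0, got {self.e0}")
        if self.emax < 0:
            raise ValueError(f"emax must be >= 0, got {self.emax}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if int(self.hill_k) != self.hill_k or self.hill_k < 1:
            raise ValueError(f"hill_k must be an integer >= 1, got {self.hill_k}")
        object.__setattr__(self, "hill_k", int(self.hill_k))


@dataclass(frozen=True)
class PKParams:
    """Pharmacokinetic parameters of the plasma-concentration equation.

    ``k1`` is the first-order clearance rate (1/time, > 0); ``k2`` couples
    clearance to the administered dose (1/(time*dose)) and may take either
    sign — a negative value models a drug whose elimination slows with
    dosing; ``h`` is the infusion gain (concentration/(time*dose), > 0).
    """

    k1: float = 0.005
    k2: float = 0.0004
    h: float = 0.001

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError(f"k1 must be > 0, got {self.k1}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")


@dataclass(frozen=True)
class TumorParams:
    """Bilinear tumor-compartment matrices.

    ``a_matrix`` holds intrinsic inter-compartment flow/growth rates (1/time),
    ``b_matrix`` the drug-effect coupling (1/(time*effect)); both are n x n.
    """

    a_matrix: NDArray[np.float64]
    b_matrix: NDArray[np.float64]

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.a_matrix, dtype=float))
        b = np.atleast_2d(np.asarray(self.b_matrix, dtype=float))
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"a_matrix must be square, got shape {a.shape}")
        if b.shape != a.shape:
            raise ValueError(
                f"b_matrix shape {b.shape} does not match a_matrix shape {a.shape}"
            )
        object.__setattr__(self, "a_matrix", a)
        object.__setattr__(self, "b_matrix", b)

    @property
    def n_compartments(self) -> int:
        return self.a_matrix.shape[0]


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter bundle: tumor, PK and PD parameters plus N(0)."""

    tumor: TumorParams
    pk: PKParams = field(default_factory=PKParams)
    pd: PDParams = field(default_factory=PDParams)
    n0: NDArray[np.float64] = None  # type: ignore[assignment]
    effect_model: str = "emax"

    def __post_init__(self) -> None:
        n = self.tumor.n_compartments
        n0 = np.ones(n) if self.n0 is None else np.atleast_1d(np.asarray(self.n0, float))
        if n0.shape != (n,):
            raise ValueError(f"n0 must have length {n}, got shape {n0.shape}")
        if np.any(n0 <= 0):
            raise ValueError("all n0 entries must be strictly positive")
        if self.effect_model not in ("emax", "sigmoid"):
            raise ValueError(
                f"effect_model must be 'emax' or 'sigmoid', got {self.effect_model!r}"
            )
        object.__setattr__(self, "n0", n0)

    # -- JSON round-trip -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "tumor": {
                "a_matrix": self.tumor.a_matrix.tolist(),
                "b_matrix": self.tumor.b_matrix.tolist(),
            },
            "pk": dataclasses.asdict(self.pk),
            "pd": dataclasses.asdict(self.pd),
            "n0": self.n0.tolist(),
            "effect_model": self.effect_model,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        return cls(
            tumor=TumorParams(**d["tumor"]),
            pk=PKParams(**d["pk"]),
            pd=PDParams(**d["pd"]),
            n0=np.asarray(d["n0"], float),
            effect_model=d.get("effect_model", "emax"),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "ModelParams":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class DoseSchedule:
    """Parametric drug-dosing schedule u(t).

    Forms
    -----
    ``constant``
        u(t) = level.
    ``cosine``
        u(t) = amplitude * cos(frequency * t) + offset; the reference study
        uses amplitude=10, frequency=0.1, offset=10 to emulate periodic
        administration.
    ``piecewise_constant``
        levels[i] on [breakpoints[i], breakpoints[i+1]); levels[0] also
        applies before the first breakpoint, levels[-1] after the last.

    The evaluated dose must be non-negative; :meth:`validate_nonnegative`
    rejects (rather than clips) schedules that dip below zero.
    """

    form: str = "cosine"
    amplitude: float = 10.0
    frequency: float = 0.1
    offset: float = 10.0
    level: float = 0.0
    breakpoints: tuple = ()
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.form not in ("constant", "cosine", "piecewise_constant"):
            raise ValueError(f"unknown schedule form {self.form!r}")
        if self.form == "cosine" and self.frequency <= 0:
            raise ValueError("cosine schedule requires frequency > 0")
        if self.form == "piecewise_constant":
            bp = tuple(float(t) for t in self.breakpoints)
            lv = tuple(float(v) for v in self.levels)
            if len(lv) != len(bp):
                raise ValueError("piecewise schedule needs one level per breakpoint")
            if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
                raise ValueError("breakpoints must be strictly increasing")
            object.__setattr__(self, "breakpoints", bp)
            object.__setattr__(self, "levels", lv)

    def __call__(self, t: ArrayLike) -> Union[float, NDArray[np.float64]]:
        t = np.asarray(t, dtype=float)
        if self.form == "constant":
            out = np.full_like(t, self.level)
        elif self.form == "cosine":
            out = self.amplitude * np.cos(self.frequency * t) + self.offset
        else:
            idx = np.clip(np.searchsorted(self.breakpoints, t, side="right") - 1, 0, None)
            out = np.asarray(self.levels, float)[idx]
        return out if out.ndim else float(out)

    def validate_nonnegative(self, times: ArrayLike) -> None:
        """Raise if u(t) < 0 anywhere on the given time grid."""
        u = np.atleast_1d(self(times))
        if np.any(u < -1e-12):
            t_bad = np.atleast_1d(np.asarray(times, float))[u < -1e-12][0]
            raise ValueError(f"dose schedule is negative at t={t_bad:g}: u={self(t_bad):g}")

    def to_dict(self) -> dict[str, Any]:
        d = {"form": self.form}
        if self.form == "constant":
            d["level"] = self.level
        elif self.form == "cosine":
            d.update(amplitude=self.amplitude, frequency=self.frequency, offset=self.offset)
        else:
            d.update(breakpoints=list(self.breakpoints), levels=list(self.levels))
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DoseSchedule":
        return cls(**d)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def effect(c: ArrayLike, pd: PDParams, effect_model: str = "emax"):
    """Pharmacodynamic effect s(c) = E0 + Emax*c^k / (EC50^k + c^k).

    ``effect_model='emax'`` forces k=1; ``'sigmoid'`` uses ``pd.hill_k``.
    The value lies in [E0, E0 + Emax) and is monotone non-decreasing in c.
    Negative concentrations are a domain error.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    k = 1 if effect_model == "emax" else pd.hill_k
    ck = c**k
    ratio = ck / (pd.ec50**k + ck)  # in [0, 1]; formed first so e0+emax bounds hold
    out = pd.e0 + pd.emax * ratio
    return out if out.ndim else float(out)


def effect_derivative(c: float, pd: PDParams, effect_model: str = "emax") -> float:
    """ds/dc, used when linearizing the coupled dynamics about a reference."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    k = 1 if effect_model == "emax" else pd.hill_k
    if c == 0.0:
        return pd.emax / pd.ec50 if k == 1 else 0.0
    denom = pd.ec50**k + c**k
    return pd.emax * k * pd.ec50**k * c ** (k - 1) / denom**2


def pk_rhs(c: float, u: float, pk: PKParams) -> float:
    """dc/dt = -(k1 + k2*u)*c + h*u."""
    return -(pk.k1 + pk.k2 * u) * c + pk.h * u


def tumor_rhs(n_vec: ArrayLike, s_val: float, tumor: TumorParams) -> NDArray[np.float64]:
    """dN/dt = (A + s*B) @ N for the bilinear tumor compartments."""
    n_vec = np.atleast_1d(np.asarray(n_vec, dtype=float))
    if n_vec.shape != (tumor.n_compartments,):
        raise ValueError(
            f"n_vec has length {n_vec.shape[0]}, expected {tumor.n_compartments}"
        )
    return (tumor.a_matrix + s_val * tumor.b_matrix) @ n_vec


# ---------------------------------------------------------------------------
# Parameter-path resolution (used by sweeps and sensitivity analysis)
# ---------------------------------------------------------------------------

#: Short names accepted by :func:`set_param` / :func:`get_param`, mapped to
#: (sub-bundle, field).  ``A`` and ``B`` address the scalar one-compartment
#: tumor matrices; ``k`` is the customary alias for the Hill exponent.
PARAM_NAMES: dict[str, tuple[str, str]] = {
    "k1": ("pk", "k1"),
    "k2": ("pk", "k2"),
    "h": ("pk", "h"),
    "e0": ("pd", "e0"),
    "emax": ("pd", "emax"),
    "ec50": ("pd", "ec50"),
    "hill_k": ("pd", "hill_k"),
    "k": ("pd", "hill_k"),
    "A": ("tumor", "a_matrix"),
    "B": ("tumor", "b_matrix"),
}


def _resolve(name: str) -> tuple[str, str]:
    if "." in name:
        bundle, fieldname = name.split(".", 1)
        if bundle in ("pk", "pd", "tumor"):
            return bundle, fieldname
    if name in PARAM_NAMES:
        return PARAM_NAMES[name]
    raise KeyError(
        f"unknown parameter {name!r}; valid names: {sorted(PARAM_NAMES)} "
        "or dotted paths like 'pk.k2'"
    )


def set_param(params: ModelParams, name: str, value: float) -> ModelParams:
    """Return a copy of ``params`` with one named parameter replaced.

    Scalar names for A and B require a one-compartment model; the Hill
    exponent is rounded to the nearest integer (the type requires one).
    """
    bundle, fieldname = _resolve(name)
    if fieldname == "hill_k":
        value = int(round(float(value)))
    sub = getattr(params, bundle)
    if bundle == "tumor" and fieldname in ("a_matrix", "b_matrix"):
        if params.tumor.n_compartments != 1 and np.isscalar(value):
            raise ValueError(
                f"scalar value for {name!r} requires a one-compartment model"
            )
        value = np.atleast_2d(np.asarray(value, float))
    new_sub = dataclasses.replace(sub, **{fieldname: value})
    return dataclasses.replace(params, **{bundle: new_sub})


def get_param(params: ModelParams, name: str) -> float:
    bundle, fieldname = _resolve(name)
    value = getattr(getattr(params, bundle), fieldname)
    if isinstance(value, np.ndarray) and value.size == 1:
        return float(value.item())
    return value
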