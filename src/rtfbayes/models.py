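"""Simulation models evaluated on time grids.

The central model is the retarded transient function (RTF), a closed-form
response curve built from a saturating sustained term and a rise-then-decay
transient term,

    f(t) = Asus * (1 - exp(-t/t1))
         + Atrans * (1 - exp(-t/t11)) * exp(-t/t2)
         + p0,

evaluated at a nonlinearly transformed time ``t`` that delays the response by
a shift parameter ``Tshift`` while leaving ``t = 0`` invariant.  A simple
first-order absorption/elimination pharmacokinetic model is registered as an
alternative, and user models can be added through :func:`register_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "RTFParameters",
    "PK2CParameters",
    "ModelSpec",
    "transform_time",
    "rtf_evaluate",
    "pk2c_evaluate",
    "get_model",
    "register_model",
    "available_models",
]

_LN10 = math.log(10.0)
# exp() overflows above ~709.78; clip exponents so MCMC excursions into
# extreme parameter regions produce finite (if saturated) values, never inf.
_EXP_CLIP = 700.0


def _safe_exp(x: np.ndarray | float) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


@dataclass(frozen=True)
class RTFParameters:
    """Parameters of the retarded transient function.

    Attributes
    ----------
    Asus : float
        Amplitude of the sustained (persistent) response, in observable units.
    t1 : float
        Timescale of the sustained response, > 0.
    Atrans : float
        Amplitude of the transient response, in observable units.
    t11 : float
        Rise timescale of the transient response, > 0.
    t2 : float
        Decay timescale of the transient response, > 0.
    Tshift : float
        Response-delay shift on the log10 domain; -2 corresponds to an
        effectively immediate response.
    p0 : float
        Baseline offset, in observable units.
    Trange : float
        Fixed range of the observation interval, > 0.  Not estimated; it
        scales the time transformation.
    """

    Asus: float
    t1: float
    Atrans: float
    t11: float
    t2: float
    Tshift: float
    p0: float
    Trange: float

    def __post_init__(self) -> None:
        for name in ("t1", "t11", "t2", "Trange"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("Asus", "Atrans", "Tshift", "p0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_dict(self) -> dict[str, float]:
        return {
            "Asus": self.Asus,
            "t1": self.t1,
            "Atrans": self.Atrans,
            "t11": self.t11,
            "t2": self.t2,
            "Tshift": self.Tshift,
            "p0": self.p0,
            "Trange": self.Trange,
        }


@dataclass(frozen=True)
class PK2CParameters:
    """First-order absorption / first-order elimination PK parameters."""

    dose: float
    ka: float
    ke: float
    V: float
    c0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ka", "ke", "V"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.dose):
            raise ValueError("dose must be finite")
        if not (np.isfinite(self.c0) and self.c0 >= 0):
            raise ValueError("c0 must be finite and >= 0")

    def as_dict(self) -> dict[str, float]:
        return {"dose": self.dose, "ka": self.ka, "ke": self.ke,
                "V": self.V, "c0": self.c0}


def transform_time(
    t_real: np.ndarray | float, Tshift: float, Trange: float
) -> np.ndarray | float:
    """Nonlinear time transformation delaying the RTF response.

    The adopted form is

        t = Trange * ( log10(10^(t_real/Trange) + 10^Tshift)
                     - log10(1 + 10^Tshift) )

    which leaves t_real = 0 invariant for every (Tshift, Trange), is strictly
    increasing in t_real, and reduces to the identity as Tshift -> -inf (an
    immediate, undelayed response).  Computed via ``logaddexp`` so large
    exponents never overflow.

    Parameters
    ----------
    t_real : array_like
        Untransformed (experimental) times, >= 0.
    Tshift : float
        Delay shift on the log10 domain.
    Trange : float
        Observation-interval range, > 0.

    Returns
    -------
    Transformed times, same shape as ``t_real``.
    """
    t = np.asarray(t_real, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t_real must be finite")
    if not np.isfinite(Tshift):
        raise ValueError("Tshift must be finite")
    if not (np.isfinite(Trange) and Trange > 0):
        raise ValueError(f"Trange must be finite and > 0, got {Trange!r}")
    a = (t / Trange) * _LN10
    c = Tshift * _LN10
    out = (Trange / _LN10) * (np.logaddexp(a, c) - np.logaddexp(0.0, c))
    return out if out.ndim else float(out)


def rtf_evaluate(
    t_real_grid: np.ndarray | Sequence[float] | float,
    params: RTFParameters | Mapping[str, float],
) -> np.ndarray:
    """Evaluate the retarded transient function on a time grid.

    ``f(0) = p0`` exactly; with ``Atrans = 0`` the curve rises monotonically
    from ``p0`` towards ``Asus + p0``.
    """
    if isinstance(params, RTFParameters):
        p = params.as_dict()
    else:
        p = dict(params)
    grid = np.atleast_1d(np.asarray(t_real_grid, dtype=float))
    if grid.size > 1 and np.any(np.diff(grid) < 0):
        raise ValueError("time grid must be sorted ascending")
    for name in ("t1", "t11", "t2", "Trange"):
        if not (np.isfinite(p[name]) and p[name] > 0):
            raise ValueError(f"{name} must be finite and > 0, got {p[name]!r}")
    t = transform_time(grid, p["Tshift"], p["Trange"])
    sustained = p["Asus"] * (1.0 - _safe_exp(-t / p["t1"]))
    transient = p["Atrans"] * (1.0 - _safe_exp(-t / p["t11"])) * _safe_exp(-t / p["t2"])
    return sustained + transient + p["p0"]


def pk2c_evaluate(
    t_real_grid: np.ndarray | Sequence[float] | float,
    params: PK2CParameters | Mapping[str, float],
) -> np.ndarray:
    """Concentration course of one-absorption/one-elimination kinetics.

    c(t) = dose*ka / (V*(ka - ke)) * (exp(-ke t) - exp(-ka t)) + c0,
    with the analytic ka -> ke limit  c(t) = dose*ka*t/V * exp(-ka t) + c0
    used when the rates coincide (relative difference below 1e-12).
    """
    if isinstance(params, PK2CParameters):
        p = params.as_dict()
    else:
        p = dict(params)
        p.setdefault("c0", 0.0)
    grid = np.atleast_1d(np.asarray(t_real_grid, dtype=float))
    if grid.size > 1 and np.any(np.diff(grid) < 0):
        raise ValueError("time grid must be sorted ascending")
    ka, ke, V, dose, c0 = p["ka"], p["ke"], p["V"], p["dose"], p["c0"]
    for name, v in (("ka", ka), ("ke", ke), ("V", V)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and > 0, got {v!r}")
    if abs(ka - ke) <= 1e-12 * max(ka, ke):
        return dose * ka * grid / V * _safe_exp(-ka * grid) + c0
    # e^{-ke t} - e^{-ka t} = e^{-ka t} * expm1((ka-ke) t); the expm1 form
    # avoids catastrophic cancellation when the rates nearly coincide
    dk = ka - ke
    with np.errstate(over="ignore"):
        diff = np.where(
            np.abs(dk * grid) < 1.0,
            _safe_exp(-ka * grid) * np.expm1(dk * grid),
            _safe_exp(-ke * grid) - _safe_exp(-ka * grid),
        )
    return (dose * ka) / (V * dk) * diff + c0


_RTF_ORDER = ("Asus", "t1", "Atrans", "t11", "t2", "Tshift", "p0", "Trange")


def _rtf_raw(t_grid: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unchecked RTF evaluation for hot loops.

    ``v`` follows ``_RTF_ORDER``; the caller guarantees positive timescales
    and a nonnegative sorted grid, so every exponent is <= 0 and the
    exponentials can only underflow (to 0), never overflow.
    """
    a = (t_grid / v[7]) * _LN10
    c = v[5] * _LN10
    tau = (v[7] / _LN10) * (np.logaddexp(a, c) - np.logaddexp(0.0, c))
    return (
        v[0] * (1.0 - np.exp(-tau / v[1]))
        + v[2] * (1.0 - np.exp(-tau / v[3])) * np.exp(-tau / v[4])
        + v[6]
    )


@dataclass(frozen=True)
class ModelSpec:
    """A registered simulation model.

    ``evaluator`` maps ``(time_grid, parameter_mapping) -> trajectory`` and
    must be deterministic for fixed inputs.  ``parameter_names`` are the
    parameters a fit estimates by default; ``fixed_parameters`` are constants
    merged into the mapping before evaluation (a fit may override them).
    """

    model_id: str
    parameter_names: tuple[str, ...]
    evaluator: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    fixed_parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.parameter_names) & set(self.fixed_parameters)
        if overlap:
            raise ValueError(
                f"parameter_names and fixed_parameters overlap: {sorted(overlap)}"
            )

    def evaluate(
        self, grid: np.ndarray, params: Mapping[str, float]
    ) -> np.ndarray:
        merged = {**self.fixed_parameters, **params}
        return self.evaluator(grid, merged)


_RTF_SPEC = ModelSpec(
    model_id="rtf",
    parameter_names=("Asus", "t1", "Atrans", "t11", "t2", "Tshift", "p0"),
    evaluator=rtf_evaluate,
    # Trange is set from the data's observation interval at fit time.
    fixed_parameters={"Trange": 1.0},
)

_PK2C_SPEC = ModelSpec(
    model_id="pk2c",
    parameter_names=("dose", "ka", "ke", "V", "c0"),
    evaluator=pk2c_evaluate,
)

_REGISTRY: dict[str, ModelSpec] = {"rtf": _RTF_SPEC, "pk2c": _PK2C_SPEC}


def get_model(model_id: str) -> ModelSpec:
    """Look up a registered model (case-sensitive)."""
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_model(spec: ModelSpec, overwrite: bool = False) -> None:
    """Register a user model under ``spec.model_id``."""
    if spec.model_id in _REGISTRY and not overwrite:
        raise ValueError(f"model {spec.model_id!r} already registered")
    _REGISTRY[spec.model_id] = spec


def available_models() -> list[str]:
    return sorted(_REGISTRY)
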