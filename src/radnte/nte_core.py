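"""Targeted + non-targeted effects (TE/NTE) damage kinetics.

The model tracks two state variables along a chronically irradiated
population: P_a, the mean probability that cells are in an NTE-induced
"activated" (stressed) state, and Y, the mean yield of lethal events per
embryo.  With dose rate R(t) in µGy/h and time in years,

    dP_a/dt = k1·R·(1 − P_a) − c3·P_a
    dY/dt   = k_bac + k_TE·R + k_NTE·P_a − κ·Y

Damage has three additive sources: background formation (k_bac), direct
targeted effects proportional to dose rate (k_TE·R), and non-targeted
effects proportional to the activated fraction (k_NTE·P_a); κ removes
damage through repair and selection.  Observed embryonic mortality is the
probability of at least one lethal event under a Poisson assumption,
P_mort = 1 − exp(−Y).

At constant dose rate the system has a closed-form solution and a unique
equilibrium; under the exponentially decaying dose rate that follows a
fallout event the system is integrated numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dose_decay import DoseDecayFit

__all__ = [
    "ModelParams",
    "SystemState",
    "AnalyticCoefficients",
    "Trajectory",
    "DegenerateDenominatorError",
    "PARAM_NAMES",
    "PARAM_UNITS",
    "ode_rhs",
    "analytic_coefficients",
    "solve_constant",
    "equilibrium",
    "solve_decaying",
    "decompose",
    "p_mort",
]

PARAM_NAMES = ("k1", "c3", "k_bac", "k_TE", "k_NTE", "kappa")
PARAM_UNITS = {
    "k1": "per uGy",
    "c3": "per year",
    "k_bac": "per year",
    "k_TE": "per uGy",
    "k_NTE": "per year",
    "kappa": "per year",
}

#: relative width of the removable-singularity guard around X1 = kappa
_DEGENERACY_RTOL = 1e-12


class DegenerateDenominatorError(ArithmeticError):
    """X1 ≈ κ: the constant-dose-rate transient formula degenerates.

    The solution itself stays finite (the singularity is removable) but the
    closed form loses all precision; integrate numerically instead.
    """


@dataclass(frozen=True)
class ModelParams:
    """The six positive rate constants of the TE/NTE kinetics.

    k1 couples dose rate (µGy/h) to cell activation per year; c3 deactivates
    (yr⁻¹); k_bac forms background damage (yr⁻¹); k_TE forms damage per unit
    dose rate; k_NTE converts the activated fraction into damage (yr⁻¹);
    kappa removes damage (yr⁻¹).  Dose rate enters in µGy/h and time in
    years throughout.
    """

    k1: float
    c3: float
    k_bac: float
    k_TE: float
    k_NTE: float
    kappa: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{f.name} must be finite and > 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParams":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def to_dict(self, with_units: bool = False) -> dict:
        if with_units:
            return {
                n: {"value": getattr(self, n), "unit": PARAM_UNITS[n]}
                for n in PARAM_NAMES
            }
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @property
    def background_yield(self) -> float:
        """Pre-exposure equilibrium damage yield k_bac/κ."""
        return self.k_bac / self.kappa


@dataclass
class SystemState:
    """(t, P_a, Y) snapshot; fields may be arrays for a vector of times."""

    t: float | np.ndarray
    Pa: float | np.ndarray
    Y: float | np.ndarray


@dataclass(frozen=True)
class AnalyticCoefficients:
    """Composite constants of the constant-dose-rate closed form."""

    X1: float
    X2: float
    X3: float


@dataclass
class Trajectory:
    """Time course of the system plus the Poisson mortality link.

    Optional channels split Y into its additive sources: Y_bac (background),
    Y_TE (targeted) and Y_NTE (non-targeted); because the Y equation is
    linear with additive sources, the channels sum to the total yield.
    """

    t: np.ndarray
    dose_rate: np.ndarray
    Pa: np.ndarray
    Y: np.ndarray
    P_mort: np.ndarray
    Y_TE: np.ndarray | None = None
    Y_NTE: np.ndarray | None = None
    Y_bac: np.ndarray | None = None
    params: ModelParams | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t_years": self.t,
            "dose_rate_uGy_h": self.dose_rate,
            "Pa": self.Pa,
            "Y": self.Y,
            "P_mort": self.P_mort,
        }
        for name in ("Y_TE", "Y_NTE", "Y_bac"):
            channel = getattr(self, name)
            if channel is not None:
                data[name] = channel
        return pd.DataFrame(data)


def ode_rhs(state, R: float, params: ModelParams) -> tuple[float, float]:
    """Right-hand side (dPa/dt, dY/dt) at dose rate R (µGy/h)."""
    Pa, Y = (state.Pa, state.Y) if isinstance(state, SystemState) else state
    dPa = params.k1 * R * (1.0 - Pa) - params.c3 * Pa
    dY = params.k_bac + params.k_TE * R + params.k_NTE * Pa - params.kappa * Y
    return dPa, dY


def analytic_coefficients(params: ModelParams, Rc: float) -> AnalyticCoefficients:
    """X1, X2, X3 of the constant-dose-rate closed form."""
    k1, c3, kb, kte, knte, kap = params.as_array()
    X1 = k1 * Rc + c3
    X2 = k1 * kte * Rc + knte * k1 + c3 * kte - kte * kap
    X3 = (
        k1 * kte * Rc**2 + ((knte + kb) * k1 + c3 * kte) * Rc + kb * c3
    ) * (X1 - kap)
    return AnalyticCoefficients(X1=X1, X2=X2, X3=X3)


def _check_degenerate(params: ModelParams, Rc: float) -> AnalyticCoefficients:
    coef = analytic_coefficients(params, Rc)
    if abs(coef.X1 - params.kappa) < _DEGENERACY_RTOL * max(coef.X1, params.kappa):
        raise DegenerateDenominatorError(
            f"X1 = k1*Rc + c3 = {coef.X1:g} coincides with kappa = "
            f"{params.kappa:g}; use the numeric solver (solve_decaying with "
            f"lam = 0) instead"
        )
    return coef


def solve_constant(params: ModelParams, Rc: float, t) -> SystemState:
    """Closed-form state under constant dose rate Rc, starting from the
    pre-exposure equilibrium (Pa = 0, Y = k_bac/κ) at t = 0.

    ``t`` may be a scalar or an array of years.
    """
    if Rc < 0:
        raise ValueError("dose rate must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    k1, c3, kb, kte, knte, kap = params.as_array()
    coef = _check_degenerate(params, Rc)
    X1, X2, X3 = coef.X1, coef.X2, coef.X3
    Pa = -(k1 * Rc * (np.exp(-X1 * t_arr) - 1.0)) / X1
    Y = (
        knte * k1 * kap * Rc * np.exp(-X1 * t_arr)
        - X1 * X2 * Rc * np.exp(-kap * t_arr)
        + X3
    ) / (kap * X1 * (X1 - kap))
    if np.isscalar(t) or t_arr.ndim == 0:
        return SystemState(t=float(t_arr), Pa=float(Pa), Y=float(Y))
    return SystemState(t=t_arr, Pa=Pa, Y=Y)


def equilibrium(params: ModelParams, Rc: float) -> tuple[float, float]:
    """Long-time limit (Pa_eq, Y_eq) under constant dose rate Rc.

    Evaluated in the cancellation-free form
    Y_eq = (k_bac + k_TE·Rc + k_NTE·Pa_eq)/κ, which is algebraically
    identical to X3/[κ·X1·(X1 − κ)] but remains well defined when X1 = κ
    (that singularity is removable).
    """
    if Rc < 0:
        raise ValueError("dose rate must be >= 0")
    Pa_eq = params.k1 * Rc / (params.k1 * Rc + params.c3)
    Y_eq = (
        params.k_bac + params.k_TE * Rc + params.k_NTE * Pa_eq
    ) / params.kappa
    return float(Pa_eq), float(Y_eq)


def p_mort(Y) -> np.ndarray | float:
    """Poisson link: probability of ≥ 1 lethal event, 1 − exp(−Y)."""
    Y_arr = np.asarray(Y, dtype=float)
    if np.any(Y_arr < 0):
        raise ValueError("damage yield Y must be >= 0")
    out = -np.expm1(-Y_arr)
    return float(out) if np.isscalar(Y) or Y_arr.ndim == 0 else out


def _default_init(params: ModelParams) -> SystemState:
    return SystemState(t=0.0, Pa=0.0, Y=params.background_yield)


_PA_TOL = 1e-6


def solve_decaying(
    params: ModelParams,
    fit: DoseDecayFit,
    t_grid,
    init: SystemState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the system under R(t) = R0·exp(−λt) on ``t_grid``.

    Adaptive LSODA integration (the activation equation is stiff whenever
    k1·R ≫ κ) with dense evaluation on the requested grid.  ``init``
    defaults to the pre-accident equilibrium at t = 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a nonempty strictly increasing 1-d array")
    if init is None:
        init = _default_init(params)
    if t_grid[0] < init.t:
        raise ValueError("t_grid must start at or after the initial time")
    k1, c3, kb, kte, knte, kap = params.as_array()
    R0, lam = fit.R0, fit.lam

    def rhs(t, y):
        R = R0 * np.exp(-lam * t)
        return [
            k1 * R * (1.0 - y[0]) - c3 * y[0],
            kb + kte * R + knte * y[0] - kap * y[1],
        ]

    def jac(t, y):
        R = R0 * np.exp(-lam * t)
        return [[-(k1 * R + c3), 0.0], [knte, -kap]]

    sol = solve_ivp(
        rhs, (init.t, t_grid[-1]), [init.Pa, init.Y],
        method="LSODA", jac=jac, rtol=rtol, atol=atol,
        t_eval=t_grid, first_step=min(1e-6, max(t_grid[-1] - init.t, 1e-9)),
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t = {sol.t[-1] if sol.t.size else init.t:g}: "
            f"{sol.message}"
        )
    Pa, Y = sol.y
    if np.any(Pa < -_PA_TOL) or np.any(Pa > 1.0 + _PA_TOL):
        raise RuntimeError("integration produced Pa outside [0, 1]")
    Pa = np.clip(Pa, 0.0, 1.0)
    return Trajectory(
        t=t_grid,
        dose_rate=R0 * np.exp(-lam * t_grid),
        Pa=Pa,
        Y=Y,
        P_mort=-np.expm1(-Y),
        params=params,
    )


def decompose(
    params: ModelParams,
    fit: DoseDecayFit,
    t_grid,
    init: SystemState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Like solve_decaying, but splits Y into its additive source channels.

    Each channel integrates dY/dt with a single source term (background
    k_bac, targeted k_TE·R, non-targeted k_NTE·P_a) and the shared removal
    −κ·Y; the P_a dynamics are unchanged.  The background channel starts at
    the pre-exposure equilibrium k_bac/κ, the radiation channels at zero, so
    the three channels sum to the total yield.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a nonempty strictly increasing 1-d array")
    if init is None:
        init = _default_init(params)
    k1, c3, kb, kte, knte, kap = params.as_array()
    R0, lam = fit.R0, fit.lam

    def rhs(t, y):
        R = R0 * np.exp(-lam * t)
        Pa = y[0]
        return [
            k1 * R * (1.0 - Pa) - c3 * Pa,
            kb - kap * y[1],
            kte * R - kap * y[2],
            knte * Pa - kap * y[3],
        ]

    sol = solve_ivp(
        rhs, (init.t, t_grid[-1]),
        [init.Pa, params.background_yield, 0.0, 0.0],
        method="LSODA", rtol=rtol, atol=atol, t_eval=t_grid,
        first_step=min(1e-6, max(t_grid[-1] - init.t, 1e-9)),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    Pa, Y_bac, Y_TE, Y_NTE = sol.y
    Y = Y_bac + Y_TE + Y_NTE
    return Trajectory(
        t=t_grid,
        dose_rate=R0 * np.exp(-lam * t_grid),
        Pa=np.clip(Pa, 0.0, 1.0),
        Y=Y,
        P_mort=-np.expm1(-Y),
        Y_TE=Y_TE,
        Y_NTE=Y_NTE,
        Y_bac=Y_bac,
        params=params,
    )
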