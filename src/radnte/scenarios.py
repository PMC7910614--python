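"""Exposure-scenario predictions: dose-response curves and time courses.

Two scenario families summarize what the fitted kinetics imply.  The
constant-rate family holds the dose rate fixed, integrates to near
equilibrium (20 years by default) and reports the radiation response — with
its targeted (TE) and non-targeted (NTE) components — across a grid of dose
rates.  The decaying family follows the response over time under
R(t) = R0·2^(−t/t_half), the post-accident situation, and locates the peak
of the transient: a response that keeps rising after the dose rate has
collapsed is the signature of persistent non-targeted damage.

Channel contributions on the mortality scale are reported as
p_mort(Y_bac + Y_channel) − p_mort(Y_bac), i.e. the excess mortality the
channel would cause on top of background alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_decay import DoseDecayFit
from .nte_core import ModelParams, Trajectory, decompose, p_mort

__all__ = [
    "Scenario",
    "PeakEstimate",
    "dose_response_constant",
    "time_course_decaying",
    "peak_time",
]

#: λ below which a "constant" scenario is treated as exactly constant
_CONST_LAM = 0.0


@dataclass(frozen=True)
class Scenario:
    """A single exposure scenario specification."""

    mode: str  # "constant" | "decaying"
    dose_rate: float  # Rc for constant, R0 for decaying (µGy/h)
    halving_time: float | None = None  # years, decaying mode
    horizon: float = 20.0
    subtract_background: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "decaying"):
            raise ValueError("mode must be 'constant' or 'decaying'")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.mode == "decaying" and (
            self.halving_time is None or self.halving_time <= 0
        ):
            raise ValueError("decaying mode needs halving_time > 0")

    @property
    def lam(self) -> float:
        if self.mode == "constant":
            return _CONST_LAM
        return float(np.log(2.0) / self.halving_time)


@dataclass(frozen=True)
class PeakEstimate:
    """Peak of a background-subtracted response transient."""

    time: float
    value: float
    censored: bool  # True when the maximum sits on the horizon boundary


def _channel_mortality(traj: Trajectory, subtract_background: bool):
    """Total/TE/NTE responses on the mortality scale at each grid time."""
    base = p_mort(traj.Y_bac)
    total = traj.P_mort - (base if subtract_background else 0.0)
    te = p_mort(traj.Y_bac + traj.Y_TE) - base
    nte = p_mort(traj.Y_bac + traj.Y_NTE) - base
    return total, te, nte


def dose_response_constant(
    params: ModelParams,
    R_grid,
    t_eval: float = 20.0,
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Radiation response after ``t_eval`` years at each constant dose rate.

    Returns a table with columns dose_rate_uGy_h, total, TE, NTE (mortality
    scale; background subtracted when requested) plus Pa and Y.
    """
    R_grid = np.asarray(R_grid, dtype=float)
    if np.any(R_grid < 0):
        raise ValueError("dose rates must be >= 0")
    if t_eval <= 0:
        raise ValueError("t_eval must be > 0")
    rows = []
    for R in R_grid:
        if R == 0.0:
            base = p_mort(params.background_yield)
            rows.append(
                {
                    "dose_rate_uGy_h": 0.0,
                    "total": 0.0 if subtract_background else base,
                    "TE": 0.0,
                    "NTE": 0.0,
                    "Pa": 0.0,
                    "Y": params.background_yield,
                }
            )
            continue
        fit = DoseDecayFit(ln_R0=float(np.log(R)), lam=_CONST_LAM,
                           method="scenario", n_points=0)
        traj = decompose(params, fit, np.array([0.0, t_eval]))
        total, te, nte = _channel_mortality(traj, subtract_background)
        rows.append(
            {
                "dose_rate_uGy_h": float(R),
                "total": float(total[-1]),
                "TE": float(te[-1]),
                "NTE": float(nte[-1]),
                "Pa": float(traj.Pa[-1]),
                "Y": float(traj.Y[-1]),
            }
        )
    return pd.DataFrame(rows)


def time_course_decaying(
    params: ModelParams,
    R0: float,
    halving_time: float,
    horizon: float = 20.0,
    n_points: int = 400,
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Response over time under a dose rate halving every ``halving_time`` yr.

    Returns a table with columns t_years, dose_rate_uGy_h, response (total,
    background-subtracted by default), TE, NTE, Pa, Y on a dense grid.
    """
    if R0 < 0:
        raise ValueError("R0 must be >= 0")
    if halving_time <= 0 or horizon <= 0:
        raise ValueError("halving_time and horizon must be > 0")
    grid = np.linspace(0.0, horizon, n_points + 1)
    if R0 == 0.0:
        base = p_mort(params.background_yield)
        resp = np.zeros_like(grid) if subtract_background else np.full_like(grid, base)
        return pd.DataFrame(
            {
                "t_years": grid,
                "dose_rate_uGy_h": np.zeros_like(grid),
                "response": resp,
                "TE": np.zeros_like(grid),
                "NTE": np.zeros_like(grid),
                "Pa": np.zeros_like(grid),
                "Y": np.full_like(grid, params.background_yield),
            }
        )
    lam = float(np.log(2.0) / halving_time)
    fit = DoseDecayFit(ln_R0=float(np.log(R0)), lam=lam,
                       method="scenario", n_points=0)
    traj = decompose(params, fit, grid)
    total, te, nte = _channel_mortality(traj, subtract_background)
    return pd.DataFrame(
        {
            "t_years": grid,
            "dose_rate_uGy_h": traj.dose_rate,
            "response": total,
            "TE": te,
            "NTE": nte,
            "Pa": traj.Pa,
            "Y": traj.Y,
        }
    )


def peak_time(course: pd.DataFrame, column: str = "response") -> PeakEstimate:
    """Locate the maximum of a scenario time course.

    Grid argmax refined by a local quadratic through the three neighbouring
    points; a maximum on the final grid point is returned as censored at the
    horizon (the transient had not peaked within the simulated window).
    """
    t = course["t_years"].to_numpy(dtype=float)
    y = course[column].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError("empty trajectory")
    i = int(np.argmax(y))
    if i == len(t) - 1:
        return PeakEstimate(time=float(t[-1]), value=float(y[-1]), censored=True)
    if i == 0:
        return PeakEstimate(time=float(t[0]), value=float(y[0]), censored=False)
    # quadratic through (t[i-1..i+1], y[i-1..i+1])
    a, b, c = np.polyfit(t[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if a < 0:
        t_pk = float(np.clip(-b / (2 * a), t[i - 1], t[i + 1]))
        y_pk = float(np.polyval([a, b, c], t_pk))
    else:  # flat or degenerate neighbourhood; keep the grid point
        t_pk, y_pk = float(t[i]), float(y[i])
    return PeakEstimate(time=t_pk, value=y_pk, censored=False)
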