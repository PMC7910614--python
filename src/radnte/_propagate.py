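"""Piecewise-analytic propagator for the TE/NTE kinetics.

Performance kernel used inside the fitting objective, where the reference
adaptive ODE integration is too slow for multi-start fits and bootstrap
resampling.  On each sub-step the dose rate is replaced by its exact average
over the step and the two-variable system is advanced with the exact
constant-dose-rate update (both equations are linear, so the one-step map is
affine and available in closed form).  The scheme is exact for a truly
constant dose rate, unconditionally stable for arbitrarily stiff activation
rates (k1·R ≫ 1), and second-order accurate in the step size; a Richardson
combination of one grid and its midpoint refinement raises that to fourth
order.  Accuracy against the reference integrator is property-tested.

Everything is vectorized over a collection of exposure series sharing one
parameter set.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Propagator", "build_grid", "propagate", "step_average_dose"]


def _phi(z: np.ndarray) -> np.ndarray:
    """(1 - exp(-z)) / z, stable at z -> 0 and for large z."""
    small = np.abs(z) < 1e-8
    zs = np.where(small, 1.0, z)
    return np.where(small, 1.0 - z / 2.0, -np.expm1(-zs) / zs)


def build_grid(obs_times, lam_max: float, *, h_target: float = 0.04,
               n_min: int = 25, n_max: int = 6000) -> np.ndarray:
    """Node grid on [0, T] dense enough that λ·h stays below ``h_target``.

    Observation times are inserted exactly so state lookups need no
    interpolation.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    T = float(obs_times.max()) if obs_times.size else 0.0
    if T <= 0.0:
        return np.array([0.0])
    n = int(np.clip(np.ceil(T * max(abs(lam_max), 0.2) / h_target), n_min, n_max))
    nodes = np.union1d(np.linspace(0.0, T, n + 1), obs_times)
    return nodes[nodes >= 0.0]


def step_average_dose(ln_R0, lam, nodes) -> np.ndarray:
    """Exact per-step average of R(t) = exp(ln_R0 − λt); shape (steps, series)."""
    ln_R0 = np.asarray(ln_R0, float)
    lam = np.asarray(lam, float)
    nodes = np.asarray(nodes, float)
    h = np.diff(nodes)[:, None]
    E = np.exp(ln_R0[None, :] - lam[None, :] * nodes[:, None])
    z = lam[None, :] * h
    with np.errstate(divide="ignore", invalid="ignore"):
        avg = (E[:-1] - E[1:]) / z
    mid = np.exp(
        ln_R0[None, :] - lam[None, :] * ((nodes[:-1] + nodes[1:]) / 2.0)[:, None]
    )
    return np.where(np.abs(z) < 1e-10, mid, avg)


def propagate(theta, ln_R0, lam, nodes, Rbar=None) -> tuple[np.ndarray, np.ndarray]:
    """Advance (Pa, Y) from the pre-exposure equilibrium along ``nodes``.

    theta = (k1, c3, k_bac, k_TE, k_NTE, kappa); ln_R0/lam give each series'
    exponential dose-rate decay.  Returns (Pa, Y) of shape
    (n_nodes, n_series).
    """
    k1, c3, kb, kte, knte, kap = map(float, theta)
    nodes = np.asarray(nodes, float)
    ln_R0 = np.asarray(ln_R0, float)
    lam = np.asarray(lam, float)
    n_steps = len(nodes) - 1
    S = len(ln_R0)
    Pa_out = np.zeros((n_steps + 1, S))
    Y_out = np.empty((n_steps + 1, S))
    Y_out[0] = kb / kap
    if n_steps == 0:
        return Pa_out, Y_out
    if Rbar is None:
        Rbar = step_average_dose(ln_R0, lam, nodes)
    h = np.diff(nodes)[:, None]

    X1 = k1 * Rbar + c3
    a = np.exp(-X1 * h)
    Pa_eq = k1 * Rbar / X1
    ek = np.exp(-kap * h[:, 0])
    # forcing integral of the constant-source part over one step
    g0 = (kb + kte * Rbar + knte * Pa_eq) * (h * _phi(kap * h))
    # exact integral of the decaying within-step Pa deviation
    dexp = knte * (ek[:, None] * h * _phi((X1 - kap) * h))

    Pa = Pa_out[0].copy()
    Y = Y_out[0].copy()
    for s in range(n_steps):
        d = Pa - Pa_eq[s]
        Y = Y * ek[s] + g0[s] + dexp[s] * d
        Pa = Pa_eq[s] + d * a[s]
        Pa_out[s + 1] = Pa
        Y_out[s + 1] = Y
    return Pa_out, Y_out


class Propagator:
    """Reusable propagation plan for a fixed exposure design.

    Precomputes, once, everything that does not depend on the model
    parameters: the coarse node grid, its midpoint refinement (for the
    Richardson combination), the per-step average dose rates on both, and
    the (node, series) position of every observation.  ``mortality(theta)``
    then costs two sweeps of the affine one-step map.
    """

    def __init__(self, ln_R0, lam, obs_times, obs_series_idx, *,
                 h_target: float = 0.04, richardson: bool = True):
        self.ln_R0 = np.asarray(ln_R0, float)
        self.lam = np.asarray(lam, float)
        self.obs_times = np.asarray(obs_times, float)
        self.obs_series_idx = np.asarray(obs_series_idx, int)
        lam_max = float(np.max(np.abs(self.lam))) if self.lam.size else 0.0
        self.richardson = richardson
        self.nodes = build_grid(self.obs_times, lam_max, h_target=h_target)
        self.idx = np.searchsorted(self.nodes, self.obs_times)
        self.Rbar = step_average_dose(self.ln_R0, self.lam, self.nodes)
        if richardson and len(self.nodes) > 1:
            mid = (self.nodes[:-1] + self.nodes[1:]) / 2.0
            self.nodes_fine = np.sort(np.concatenate([self.nodes, mid]))
            self.idx_fine = np.searchsorted(self.nodes_fine, self.obs_times)
            self.Rbar_fine = step_average_dose(
                self.ln_R0, self.lam, self.nodes_fine
            )
        else:
            self.richardson = False

    def yields(self, theta) -> np.ndarray:
        """Damage yield Y at each observation."""
        _, Y1 = propagate(theta, self.ln_R0, self.lam, self.nodes, self.Rbar)
        y1 = Y1[self.idx, self.obs_series_idx]
        if not self.richardson:
            return y1
        _, Y2 = propagate(
            theta, self.ln_R0, self.lam, self.nodes_fine, self.Rbar_fine
        )
        y2 = Y2[self.idx_fine, self.obs_series_idx]
        return (4.0 * y2 - y1) / 3.0

    def mortality(self, theta) -> np.ndarray:
        """P_mort = 1 − exp(−Y) at each observation."""
        return -np.expm1(-np.maximum(self.yields(theta), 0.0))
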