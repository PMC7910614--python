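"""Synthetic observation datasets with the structure the analysis assumes.

Generated data mimic the field studies: a handful of locations, each with
its own initial dose rate and exponential decay constant, sparsely sampled
over the first decade after an accident, with mortality produced by the
TE/NTE kinetics and degraded by observation noise.  Default shapes span the
ranges seen in the packaged Chernobyl tables (about a dozen locations, 1–6
sampling years each, ln R0 in [0, 11] ln µGy/h, λ in [0, 0.5] yr⁻¹); the
default noise model is binomial, because observed mortality is a proportion
of scored embryos, with 50 embryos per observation; the default generating
parameters are the rodent-scale rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from . import _propagate
from .data_io import Dataset
from .dose_decay import DoseDecayFit
from .nte_core import ModelParams

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "RODENT_LIKE_PARAMS"]

#: default generating parameters: rodent-scale kinetics (slow deactivation
#: and slow damage removal, so transgenerational damage accumulates).
RODENT_LIKE_PARAMS = ModelParams(
    k1=0.323, c3=4.54e-5, k_bac=1.07e-6, k_TE=3.17e-9, k_NTE=0.025,
    kappa=4.80e-5,
)


@dataclass
class SyntheticConfig:
    """Shape, exposure ranges, generating parameters and noise model."""

    n_locations: int = 12
    times_per_location: int | tuple[int, int] = (1, 6)
    ln_R0_range: tuple[float, float] = (0.0, 11.0)
    lam_range: tuple[float, float] = (0.0, 0.5)
    true_params: ModelParams = field(default_factory=lambda: RODENT_LIKE_PARAMS)
    noise_model: str = "binomial"  # "none" | "gaussian" | "binomial"
    noise_sd: float = 0.02         # gaussian only
    n_embryos: int = 50            # binomial only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ValueError("need at least one location")
        if self.ln_R0_range[0] > self.ln_R0_range[1]:
            raise ValueError("ln_R0_range must be ordered")
        if self.lam_range[0] > self.lam_range[1]:
            raise ValueError("lam_range must be ordered")
        if self.noise_model not in ("none", "gaussian", "binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "gaussian" and self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.noise_model == "binomial" and self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")


@dataclass
class SyntheticTruth:
    """Generating parameters and noise-free per-row values."""

    params: ModelParams
    decay_fits: dict[str, DoseDecayFit]
    true_mortality: np.ndarray

    def to_json(self, path) -> None:
        doc = {
            "params": self.params.to_dict(),
            "decay": {
                s: {"ln_R0": f.ln_R0, "lam": f.lam}
                for s, f in self.decay_fits.items()
            },
            "true_mortality": self.true_mortality.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def generate(config: SyntheticConfig | None = None) -> tuple[Dataset, SyntheticTruth]:
    """Draw one synthetic dataset plus its generating truth.

    Deterministic given ``config.seed``.  Each location draws (ln R0, λ)
    uniformly from the configured ranges and a sorted set of whole-year
    sampling times in [1, 10]; dose rates follow the decay law exactly;
    true mortality comes from the model with pre-accident-equilibrium
    initial conditions; noise is then applied to the mortality column only.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    tpl = config.times_per_location
    lo_t, hi_t = (tpl, tpl) if isinstance(tpl, int) else tpl

    rows = []
    decay_fits: dict[str, DoseDecayFit] = {}
    for i in range(config.n_locations):
        label = f"loc{i + 1:02d}"
        ln_R0 = rng.uniform(*config.ln_R0_range)
        lam = rng.uniform(*config.lam_range)
        n_times = rng.integers(lo_t, hi_t + 1)
        times = np.sort(rng.choice(np.arange(1, 11), size=min(n_times, 10),
                                   replace=False)).astype(float)
        decay_fits[label] = DoseDecayFit(
            ln_R0=ln_R0, lam=lam, method="synthetic", n_points=len(times),
        )
        for t in times:
            rows.append(
                {
                    "location": label,
                    "time_years": t,
                    "dose_rate_uGy_h": float(np.exp(ln_R0 - lam * t)),
                }
            )
    frame = pd.DataFrame(rows)

    labels = list(decay_fits)
    pos = {s: j for j, s in enumerate(labels)}
    prop = _propagate.Propagator(
        ln_R0=[decay_fits[s].ln_R0 for s in labels],
        lam=[decay_fits[s].lam for s in labels],
        obs_times=frame["time_years"].to_numpy(float),
        obs_series_idx=frame["location"].map(pos).to_numpy(),
        h_target=0.01,
    )
    true_p = prop.mortality(config.true_params.as_array())

    if config.noise_model == "none":
        observed = true_p.copy()
    elif config.noise_model == "gaussian":
        observed = np.clip(
            true_p + rng.normal(0.0, config.noise_sd, size=len(true_p)),
            0.0, 1.0,
        )
    else:
        observed = rng.binomial(config.n_embryos, true_p) / config.n_embryos

    frame["mortality"] = observed
    dataset = Dataset(name="synthetic", frame=frame)
    truth = SyntheticTruth(
        params=config.true_params,
        decay_fits=decay_fits,
        true_mortality=true_p,
    )
    return dataset, truth
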