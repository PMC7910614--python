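import numpy as np
import pytest

from radnte.data_io import load_fixture, load_reference_params
from radnte.dose_decay import DoseDecayFit
from radnte.nte_core import ModelParams


@pytest.fixture(scope="session")
def plant_ds():
    return load_fixture("plant")


@pytest.fixture(scope="session")
def rodent_ds():
    return load_fixture("rodent")


@pytest.fixture(scope="session")
def plant_params():
    return ModelParams.from_dict(load_reference_params("plant")["params"])


@pytest.fixture(scope="session")
def rodent_params():
    return ModelParams.from_dict(load_reference_params("rodent")["params"])


def printed_decay_fits(dataset):
    """Per-series decay fits taken from the reference intercept/slope columns.

    A printed slope of 0.00 is mapped to the near-zero fallback value used
    for single-time series, matching how those lines were produced.
    """
    fits = {}
    for label, sub in dataset.frame.groupby("series", sort=False):
        a = float(sub["ref_intercept"].iloc[0])
        b = float(sub["ref_slope"].iloc[0])
        fits[label] = DoseDecayFit(
            ln_R0=a, lam=b if b > 0 else 1e-3, n_points=len(sub)
        )
    return fits


@pytest.fixture(scope="session")
def plant_printed_fits(plant_ds):
    return printed_decay_fits(plant_ds)


@pytest.fixture(scope="session")
def rodent_printed_fits(rodent_ds):
    return printed_decay_fits(rodent_ds)


def draw_params(rng, lo=-6.0, hi=1.5):
    """Random positive rate constants, log-uniform across decades."""
    return ModelParams.from_array(10.0 ** rng.uniform(lo, hi, 6))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
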