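"""Observation tables for multigenerational radiation-mortality analysis.

The analysis consumes tables of (location, years since the accident, ambient
dose rate, embryonic-mortality probability).  Two such tables are packaged as
fixtures: embryonic mortality in *Arabidopsis thaliana* ("plant", 35 rows, 14
locations) and in bank voles *Clethrionomys glareolus* ("rodent", 12 rows, 3
sites), both collected in the Chernobyl accident region during the first
decade after 1986.  The fixtures additionally carry the per-location
ln-dose-rate regression line (``ref_intercept``/``ref_slope``) and the
originally reported model-fitted mortality (``ref_fitted``) as reference
columns; the pipeline never reads them, tests do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Observation",
    "Dataset",
    "SchemaError",
    "DataValidationError",
    "FIXTURES",
    "load_fixture",
    "load_reference_params",
    "read_observations",
    "write_observations",
    "convert_dose_rate",
]

REQUIRED_COLUMNS = ("location", "time_years", "dose_rate_uGy_h", "mortality")
REFERENCE_COLUMNS = ("ref_intercept", "ref_slope", "ref_fitted")
FIXTURES = ("plant", "rodent")

#: hours per averaging period used when converting reported doses to µGy/h
_PERIOD_HOURS = {"month": 30.0 * 24.0, "day": 24.0, "hour": 1.0}


class SchemaError(ValueError):
    """Input table is structurally unusable (missing columns, empty file)."""


class DataValidationError(ValueError):
    """A row violates an observation invariant; message carries the row."""


@dataclass(frozen=True)
class Observation:
    """One (location, time, dose rate, mortality) record.

    time is years since the 1986 accident; dose_rate is in µGy/h; mortality
    is a probability of embryonic death in [0, 1].
    """

    location: str
    time: float
    dose_rate: float
    mortality: float
    series: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite([self.time, self.dose_rate, self.mortality]).all():
            raise DataValidationError(f"non-finite value in observation {self}")
        if self.time < 0:
            raise DataValidationError(f"time must be >= 0, got {self.time}")
        if self.dose_rate < 0:
            raise DataValidationError(f"dose_rate must be >= 0, got {self.dose_rate}")
        if not 0.0 <= self.mortality <= 1.0:
            raise DataValidationError(
                f"mortality must be in [0, 1], got {self.mortality}"
            )
        if not self.series:
            object.__setattr__(self, "series", self.location)


@dataclass
class Dataset:
    """A named, ordered collection of observations backed by a DataFrame.

    ``frame`` always has the columns location, time_years, dose_rate_uGy_h,
    mortality plus a derived ``series`` column: the grouping label used for
    per-series dose-rate-decay fitting.  A series is normally a location; when
    reference regression columns are present and a location carries more than
    one distinct (intercept, slope) pair — e.g. a site sampled both under
    background and contaminated conditions — each pair becomes its own series.
    """

    name: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.observations)

    @property
    def observations(self) -> list[Observation]:
        return [
            Observation(
                location=row.location,
                time=float(row.time_years),
                dose_rate=float(row.dose_rate_uGy_h),
                mortality=float(row.mortality),
                series=row.series,
            )
            for row in self.frame.itertuples(index=False)
        ]

    @property
    def series_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.frame["series"]:
            seen.setdefault(s, None)
        return list(seen)

    def resample(self, rng: np.random.Generator) -> "Dataset":
        """Case bootstrap: draw rows with replacement, same size."""
        idx = rng.integers(0, len(self.frame), size=len(self.frame))
        frame = self.frame.iloc[idx].reset_index(drop=True)
        return Dataset(name=f"{self.name}*", frame=frame)


def _assign_series(frame: pd.DataFrame) -> pd.Series:
    if {"ref_intercept", "ref_slope"}.issubset(frame.columns):
        keys = list(
            zip(frame["location"], frame["ref_intercept"], frame["ref_slope"])
        )
        per_location: dict[str, list] = {}
        for loc, a, b in dict.fromkeys(keys):
            per_location.setdefault(loc, []).append((a, b))
        labels = []
        for loc, a, b in keys:
            variants = per_location[loc]
            if len(variants) == 1:
                labels.append(loc)
            else:
                labels.append(f"{loc}#{variants.index((a, b)) + 1}")
        return pd.Series(labels, index=frame.index)
    return frame["location"].astype(str)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; need {list(REQUIRED_COLUMNS)}"
        )
    if len(frame) == 0:
        raise SchemaError("observation table is empty")
    frame = frame.reset_index(drop=True).copy()
    for col in ("time_years", "dose_rate_uGy_h", "mortality"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    problems = []
    for i, row in frame.iterrows():
        if row[["time_years", "dose_rate_uGy_h", "mortality"]].isna().any():
            problems.append(f"row {i}: non-numeric value")
        elif not 0.0 <= row["mortality"] <= 1.0:
            problems.append(f"row {i}: mortality {row['mortality']} outside [0, 1]")
        elif row["time_years"] < 0:
            problems.append(f"row {i}: negative time {row['time_years']}")
        elif row["dose_rate_uGy_h"] < 0:
            problems.append(f"row {i}: negative dose rate {row['dose_rate_uGy_h']}")
    if problems:
        raise DataValidationError("; ".join(problems))
    frame["location"] = frame["location"].astype(str)
    frame["series"] = _assign_series(frame)
    return frame


def _fixture_path(filename: str):
    return resources.files("radnte.data").joinpath(filename)


def load_fixture(name: str) -> Dataset:
    """Load a packaged observation table ("plant" or "rodent")."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available fixtures: {sorted(FIXTURES)}"
        )
    with resources.as_file(_fixture_path(f"{name}.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    return Dataset(name=name, frame=frame)


def load_reference_params(name: str) -> dict:
    """Best-fit parameter sets from the original Chernobyl analysis.

    Returns a dict with keys ``params`` (the six rate constants), ``units``
    and ``ci95``.  Censored CI bounds are kept as strings (e.g. ``">1e2"``).
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {sorted(FIXTURES)}"
        )
    with resources.as_file(_fixture_path(f"{name}_params.json")) as path:
        return json.loads(Path(path).read_text())


def read_observations(path, fmt: str | None = None, name: str | None = None) -> Dataset:
    """Read a delimited observation table (TSV by default, CSV by extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown table format {fmt!r}; use 'tsv' or 'csv'")
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty") from exc
    return Dataset(name=name or path.stem, frame=frame)


def write_observations(dataset: Dataset, path, fmt: str | None = None) -> None:
    """Write a Dataset back to delimited text (inverse of read_observations)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}[fmt]
    cols = [c for c in dataset.frame.columns if c != "series"]
    dataset.frame[cols].to_csv(path, sep=sep, index=False)


def convert_dose_rate(value: float, period: str) -> float:
    """Convert a dose accumulated per period (month/day/hour) to µGy/h.

    A month is taken as 30 × 24 h, so e.g. 720 µGy/month → 1.0 µGy/h and
    0.05 µGy/day → 0.00208 µGy/h.
    """
    if period not in _PERIOD_HOURS:
        raise ValueError(f"unknown period {period!r}; use month, day or hour")
    value = float(value)
    if value < 0:
        raise DataValidationError(f"dose must be >= 0, got {value}")
    return value / _PERIOD_HOURS[period]
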