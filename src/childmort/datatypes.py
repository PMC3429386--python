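"""Core domain types for under-five mortality estimation.

Conventions used throughout the package:

* ``5q0`` (U5MR) is the probability that a newborn dies before exact age
  five.  Observation tables and trend estimates carry it per 1,000 live
  births; latent trajectories carry it as a probability in (0, 1).
* Observation tables are pandas DataFrames with the columns in
  :data:`OBS_COLUMNS`; birth-history tables use :data:`BH_COLUMNS`.
* ``ref_time`` is a decimal year (the midpoint of the reference period).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SOURCE_TYPES = ("vr_complete", "vr_incomplete", "survey_direct", "survey_indirect")
VR_TYPES = ("vr_complete", "vr_incomplete")

#: canonical observation-table schema
OBS_COLUMNS = [
    "country_id",
    "ref_time",
    "value_per1000",
    "source_id",
    "source_type",
    "sampling_se",
    "excluded",
    "duplicate_of",
]

#: canonical birth-history schema; death_age_months is NaN for children
#: alive (right-censored) at the survey date
BH_COLUMNS = ["woman_id", "child_id", "birth_year_decimal", "death_age_months", "survey_year"]

#: demographic-input schema
DEMO_COLUMNS = ["country_id", "year", "births", "pop_age0", "pop_age1to4"]


@dataclass
class SourceSpec:
    """One data series feeding a country's observation table.

    Parameters
    ----------
    source_id : str
        Unique series label (e.g. ``"VR"`` or ``"DHS-2005"``).
    source_type : str
        One of ``vr_complete``, ``vr_incomplete``, ``survey_direct``,
        ``survey_indirect``.
    bias_factor : float
        Multiplicative systematic bias on the true 5q0 (1 = unbiased;
        incomplete vital registration typically has a factor below 1).
    sampling_cv : float
        Coefficient of variation of the sampling error; the generator
        draws lognormal noise with this log-scale SD.
    years_covered : sequence of int
        Reference years at which the series reports a value.
    survey_year : int, optional
        Fieldwork year for retrospective (survey) sources; must be at or
        after the last covered year.
    """

    source_id: str
    source_type: str
    bias_factor: float = 1.0
    sampling_cv: float = 0.0
    years_covered: Sequence[int] = field(default_factory=tuple)
    survey_year: int | None = None

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        if self.bias_factor <= 0:
            raise ValueError("bias_factor must be positive")
        if self.sampling_cv < 0:
            raise ValueError("sampling_cv must be nonnegative")
        if self.source_type == "vr_complete" and self.bias_factor != 1.0:
            raise ValueError("complete VR must have bias_factor = 1")
        self.years_covered = tuple(int(y) for y in self.years_covered)
        if self.source_type.startswith("survey") and self.survey_year is not None:
            if self.years_covered and self.survey_year < max(self.years_covered):
                raise ValueError("survey_year must be >= last covered year")

    @property
    def is_vr(self) -> bool:
        return self.source_type in VR_TYPES


@dataclass
class ScenarioConfig:
    """Full description of one synthetic country scenario.

    ``trend_knots`` are (year, log10 5q0) pairs; the latent trajectory is
    piecewise-linear between them on the log10 scale.  ``conflict_spike``
    is an optional (year, multiplier, duration_years) triple applied
    multiplicatively to 5q0.
    """

    country_id: str
    year_range: tuple[int, int]
    trend_knots: Sequence[tuple[float, float]]
    sources: Sequence[SourceSpec] = field(default_factory=list)
    conflict_spike: tuple[int, float, int] | None = None
    births_per_year: float = 100_000.0
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.year_range
        if y1 - y0 < 9:
            raise ValueError("year_range must span at least 10 years")
        knot_years = [k[0] for k in self.trend_knots]
        if any(b <= a for a, b in zip(knot_years, knot_years[1:])):
            raise ValueError("trend_knots years must be strictly increasing")
        if any(not (y0 <= y <= y1) for y in knot_years):
            raise ValueError("trend_knots years must lie within year_range")
        if any(not (0.0 < 10.0 ** v < 1.0) for _, v in self.trend_knots):
            raise ValueError("trend_knots imply 5q0 outside (0, 1)")
        if self.births_per_year <= 0:
            raise ValueError("births_per_year must be positive")
        if self.conflict_spike is not None:
            _, mult, dur = self.conflict_spike
            if mult <= 1:
                raise ValueError("conflict multiplier must exceed 1")
            if dur < 1:
                raise ValueError("conflict duration must be >= 1 year")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


@dataclass
class TrueTrajectory:
    """Latent yearly mortality and demography for one country.

    All probabilities are unitless (not per 1,000): ``q5`` is the
    probability of dying before age five, ``q1`` before age one.
    """

    country_id: str
    years: np.ndarray
    q5: np.ndarray
    q1: np.ndarray
    births: np.ndarray
    pop_age0: np.ndarray
    pop_age1to4: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for name in ("q5", "q1", "births", "pop_age0", "pop_age1to4"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.years.shape:
                raise ValueError(f"{name} must align with years")
            setattr(self, name, arr)
        if np.any((self.q5 <= 0) | (self.q5 >= 1)):
            raise ValueError("q5 must lie in (0, 1)")
        if np.any((self.q1 <= 0) | (self.q1 > self.q5)):
            raise ValueError("q1 must lie in (0, q5]")
        if np.any(self.births < 0) or np.any(self.pop_age0 < 0) or np.any(self.pop_age1to4 < 0):
            raise ValueError("counts must be nonnegative")

    def q5_at(self, years: np.ndarray) -> np.ndarray:
        """5q0 at the given years (exact lookup, integer years)."""
        idx = np.searchsorted(self.years, np.asarray(years, dtype=int))
        if np.any(idx >= len(self.years)) or np.any(self.years[np.clip(idx, 0, None)] != years):
            raise KeyError("year outside trajectory")
        return self.q5[idx]

    def demographics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country_id": self.country_id,
                "year": self.years,
                "births": self.births,
                "pop_age0": self.pop_age0,
                "pop_age1to4": self.pop_age1to4,
            }
        )


@dataclass
class TrendEstimate:
    """Fitted yearly U5MR series, per 1,000 live births.

    ``scale_value`` is the fit on the transform (log10) scale; ``lower``
    and ``upper`` are 95% bounds where the method provides them.
    """

    country_id: str
    years: np.ndarray
    r_hat: np.ndarray
    method: str
    scale_value: np.ndarray | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.r_hat = np.asarray(self.r_hat, dtype=float)
        if self.years.shape != self.r_hat.shape:
            raise ValueError("years and r_hat must align")
        if np.any(self.r_hat <= 0):
            raise ValueError("r_hat must be positive")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")

    def at(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=int)
        idx = np.searchsorted(self.years, years)
        if np.any(idx >= len(self.years)) or np.any(self.years[np.clip(idx, 0, None)] != years):
            missing = sorted(set(np.atleast_1d(years).tolist()) - set(self.years.tolist()))
            raise KeyError(f"trend estimate missing years {missing}")
        return self.r_hat[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"country_id": self.country_id, "year": self.years, "method": self.method, "r_hat": self.r_hat}
        )
        df["lower"] = self.lower if self.lower is not None else np.nan
        df["upper"] = self.upper if self.upper is not None else np.nan
        return df


@dataclass
class DeathsSeries:
    """Yearly under-five deaths (possibly fractional) from one method."""

    country_id: str
    years: np.ndarray
    deaths: np.ndarray
    method: str  # "rate_method" | "cohort_method"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        if self.years.shape != self.deaths.shape:
            raise ValueError("years and deaths must align")
        if np.any(self.deaths < -1e-9):
            raise ValueError("deaths must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"country_id": self.country_id, "year": self.years, "method": self.method, "deaths": self.deaths}
        )


def empty_observations() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        OBS_COLUMNS,
        [str, float, float, str, str, float, bool, object],
    )})
    return df


def check_observations(df: pd.DataFrame) -> None:
    """Raise ValueError if an observation table violates the schema."""
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns {missing}")
    if len(df) == 0:
        return
    if (df["value_per1000"] <= 0).any():
        raise ValueError("value_per1000 must be positive")
    if (df["sampling_se"] < 0).any():
        raise ValueError("sampling_se must be nonnegative")
    bad = set(df["source_type"]) - set(SOURCE_TYPES)
    if bad:
        raise ValueError(f"unknown source_type values {sorted(bad)}")


def active_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Records eligible for fitting: excluded flags honoured."""
    if "excluded" not in df.columns:
        return df
    return df[~df["excluded"].astype(bool)]
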