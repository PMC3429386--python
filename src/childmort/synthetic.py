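"""Synthetic country scenarios: latent trajectories, observation tables,
and full birth histories.

The generator emulates the data landscape a child-mortality estimation
group faces: several overlapping series per country (complete or
incomplete vital registration, direct and indirect survey series), each
with its own systematic bias and heteroskedastic sampling error, and
typically no data for the most recent years.  Observation noise is
lognormal — normal on the log scale — which keeps values positive and
matches the log-scale trend-fitting convention used by the estimation
modules.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BH_COLUMNS,
    OBS_COLUMNS,
    VR_TYPES,
    ScenarioConfig,
    SourceSpec,
    TrueTrajectory,
)

__all__ = [
    "generate_trajectory",
    "generate_observations",
    "generate_birth_histories",
    "apply_vr_adjustment",
    "flag_consistently_low_series",
    "generate_scenario",
]


def _two_band_hazards(q1: np.ndarray, q5: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Constant hazards (per year) on ages 0-1 and 1-5 matching q1, q5."""
    q4_1 = 1.0 - (1.0 - q5) / (1.0 - q1)
    h0 = -np.log1p(-q1)
    h1 = -np.log1p(-q4_1) / 4.0
    return h0, h1


def _stationary_person_years(q1: np.ndarray, q5: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Person-years lived in [0,1) and [1,5) per birth under the two-band
    constant-hazard schedule (stationary-population approximation)."""
    h0, h1 = _two_band_hazards(q1, q5)
    l1 = np.exp(-h0)
    py0 = np.where(h0 > 0, (1.0 - l1) / h0, 1.0)
    py14 = np.where(h1 > 0, l1 * (1.0 - np.exp(-4.0 * h1)) / h1, 4.0 * l1)
    return py0, py14


def generate_trajectory(config: ScenarioConfig) -> TrueTrajectory:
    """Build the latent yearly trajectory for a scenario.

    5q0 is the exponential (base 10) of piecewise-linear interpolation of
    the trend knots on the log10 scale; an optional conflict spike
    multiplies 5q0 over its duration.  The infant share defaults to a
    constant split 1q0 = split_fraction x 5q0.  Population counts are the
    stationary person-years implied by each year's schedule and the
    (constant) yearly births.
    """
    years = config.years
    ky = np.array([k[0] for k in config.trend_knots], dtype=float)
    kv = np.array([k[1] for k in config.trend_knots], dtype=float)
    log_q5 = np.interp(years.astype(float), ky, kv)
    q5 = 10.0 ** log_q5
    if config.conflict_spike is not None:
        y0, mult, dur = config.conflict_spike
        mask = (years >= y0) & (years < y0 + dur)
        q5 = np.where(mask, q5 * mult, q5)
    if np.any(q5 >= 1.0):
        raise ValueError(
            "trajectory invalid: 5q0 reaches or exceeds 1 after applying the conflict spike"
        )
    q1 = config.split_fraction * q5
    births = np.full(years.shape, float(config.births_per_year))
    py0, py14 = _stationary_person_years(q1, q5)
    return TrueTrajectory(
        country_id=config.country_id,
        years=years,
        q5=q5,
        q1=q1,
        births=births,
        pop_age0=births * py0,
        pop_age1to4=births * py14,
    )


def generate_observations(
    traj: TrueTrajectory,
    sources: Sequence[SourceSpec],
    seed: int,
) -> pd.DataFrame:
    """Realize an observation table from a trajectory and source specs.

    Each record's value (per 1,000) is ``1000 * q5 * bias_factor * exp(e)``
    with ``e ~ N(0, sampling_cv^2)``, independent across records;
    ``sampling_se = value * sampling_cv``.  Deterministic for fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in sources:
        yrs = np.array(sorted(spec.years_covered), dtype=int)
        if len(yrs) == 0:
            continue
        q5 = traj.q5_at(yrs)
        eps = rng.normal(0.0, spec.sampling_cv, size=len(yrs)) if spec.sampling_cv > 0 else np.zeros(len(yrs))
        value = 1000.0 * q5 * spec.bias_factor * np.exp(eps)
        for y, v in zip(yrs, value):
            rows.append(
                {
                    "country_id": traj.country_id,
                    "ref_time": float(y),
                    "value_per1000": v,
                    "source_id": spec.source_id,
                    "source_type": spec.source_type,
                    "sampling_se": v * spec.sampling_cv,
                    "excluded": False,
                    "duplicate_of": None,
                }
            )
    if not rows:
        return pd.DataFrame(columns=OBS_COLUMNS)
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def _yearly_hazard_segments(traj: TrueTrajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    years = traj.years.astype(float)
    h0, h1 = _two_band_hazards(traj.q1, traj.q5)
    return years, h0, h1


def _simulate_death_age(
    birth: float,
    years: np.ndarray,
    h0: np.ndarray,
    h1: np.ndarray,
    exp_draw: float,
) -> float:
    """Invert the cumulative two-band, period-varying hazard for one child.

    Returns the exact death age in years, or inf if the child survives to
    age five.  Hazard segments break at calendar year boundaries and at
    age one; years beyond the trajectory hold the boundary schedule.
    """
    age = 0.0
    remaining = exp_draw
    while age < 5.0:
        t = birth + age
        yi = int(np.clip(np.floor(t) - years[0], 0, len(years) - 1))
        haz = h0[yi] if age < 1.0 else h1[yi]
        seg_end = min(np.floor(t) + 1.0 - t, (1.0 if age < 1.0 else 5.0) - age)
        seg_end = max(seg_end, 1e-12)
        if haz * seg_end >= remaining:
            return age + (remaining / haz if haz > 0 else np.inf)
        remaining -= haz * seg_end
        age += seg_end
    return np.inf


def generate_birth_histories(
    traj: TrueTrajectory,
    n_women: int,
    fertility_rate: float,
    survey_year: float,
    seed: int,
    reproductive_window: float = 15.0,
) -> pd.DataFrame:
    """Simulate a full-birth-history survey table.

    Each woman's births form a Poisson process at ``fertility_rate``
    (births/woman/year) over the ``reproductive_window`` years before the
    survey (clipped to the trajectory's span).  Child deaths follow the
    two-band piecewise-constant hazards consistent with each period's
    q1/q5; children alive at the survey date are right-censored
    (``death_age_months`` NaN).  Deterministic for a fixed seed.
    """
    if fertility_rate <= 0:
        raise ValueError("fertility_rate must be positive")
    if n_women <= 0:
        raise ValueError("n_women must be positive")
    if not (traj.years[0] <= survey_year <= traj.years[-1] + 1):
        raise ValueError("survey_year must fall within the trajectory years")
    rng = np.random.default_rng(seed)
    years, h0, h1 = _yearly_hazard_segments(traj)
    window_start = max(float(traj.years[0]), survey_year - reproductive_window)
    window = survey_year - window_start

    n_births = rng.poisson(fertility_rate * window, size=n_women)
    rows: list[tuple] = []
    for w in range(n_women):
        k = n_births[w]
        if k == 0:
            continue
        births = np.sort(window_start + rng.uniform(0.0, window, size=k))
        draws = rng.exponential(1.0, size=k)
        for c, (b, e) in enumerate(zip(births, draws)):
            death_age = _simulate_death_age(b, years, h0, h1, e)
            if np.isfinite(death_age) and b + death_age < survey_year:
                rec_age = death_age * 12.0
            else:
                rec_age = np.nan  # alive at survey (or beyond age five)
            rows.append((f"w{w}", f"w{w}c{c}", b, rec_age, float(survey_year)))
    return pd.DataFrame(rows, columns=BH_COLUMNS)


def apply_vr_adjustment(records: pd.DataFrame, factor: float) -> pd.DataFrame:
    """Apply a single multiplicative completeness correction to a VR series.

    Mirrors the practice of adjusting under-reported European VR upward by
    a fixed country-specific factor (e.g. 10% or 20%) across the entire
    time series.  Both the value and its sampling SE are scaled.
    """
    if factor <= 0:
        raise ValueError("adjustment factor must be positive")
    non_vr = set(records["source_type"]) - set(VR_TYPES)
    if non_vr:
        raise ValueError(f"VR adjustment applied to non-VR source types {sorted(non_vr)}")
    out = records.copy()
    out["value_per1000"] = out["value_per1000"] * factor
    out["sampling_se"] = out["sampling_se"] * factor
    return out


def flag_consistently_low_series(
    records: pd.DataFrame,
    reference_sources: Iterable[str] | None = None,
    window: float = 1.0,
) -> pd.DataFrame:
    """Flag sources that sit below every other series wherever they overlap.

    A source is excluded iff at every one of its observation times some
    reference observation lies within ``window`` years AND all such
    overlapping reference values exceed the source's value.  A source with
    no overlap anywhere is left unflagged with a warning.  Flagged records
    keep their data; only ``excluded`` is set.
    """
    sources = list(dict.fromkeys(records["source_id"]))
    if len(sources) < 2:
        raise ValueError("need at least two sources to apply the exclusion rule")
    ref_ids = set(reference_sources) if reference_sources is not None else None
    out = records.copy()
    for sid in sources:
        own = records[records["source_id"] == sid]
        others = records[records["source_id"] != sid]
        if ref_ids is not None:
            others = others[others["source_id"].isin(ref_ids)]
        if len(others) == 0:
            continue
        any_overlap = False
        all_below = True
        for _, row in own.iterrows():
            near = others[np.abs(others["ref_time"] - row["ref_time"]) <= window]
            if len(near) == 0:
                continue
            any_overlap = True
            if not (row["value_per1000"] < near["value_per1000"]).all():
                all_below = False
                break
        if not any_overlap:
            warnings.warn(
                f"source {sid!r} has no overlap with reference sources; left unflagged",
                stacklevel=2,
            )
            continue
        if all_below:
            out.loc[out["source_id"] == sid, "excluded"] = True
    return out


def generate_scenario(config: ScenarioConfig) -> tuple[TrueTrajectory, pd.DataFrame]:
    """Convenience: trajectory plus observation table from one config."""
    traj = generate_trajectory(config)
    obs = generate_observations(traj, config.sources, seed=config.seed)
    return traj, obs
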