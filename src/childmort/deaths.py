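"""Yearly under-five death counts from a fitted U5MR trend.

Two estimators are implemented, matching the two groups' practice:

* ``deaths_rate_method`` — convert each year's 5q0 into central
  mortality rates for ages 0 and 1-4 via the life-table identity
  ``m = q / (n - q (n - a))`` and multiply by the population in each
  band.
* ``deaths_cohort_method`` — split each yearly birth cohort into 52
  birth-week cohorts, age them deterministically under piecewise-
  constant weekly hazards derived from the period schedule (hazards
  switch at calendar-year boundaries and at age one), and allocate each
  death to the calendar year in which it occurs.

The two agree under a time-constant schedule with a consistent
stationary population; they differ when mortality is changing, which is
exactly the discrepancy the decomposition module quantifies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DeathsSeries, TrendEstimate

__all__ = [
    "split_q5",
    "q_to_m",
    "deaths_rate_method",
    "deaths_cohort_method",
]

WEEKS_PER_YEAR = 52  # 364-day year convention


def split_q5(q5, split_fraction: float = 0.7):
    """Split 5q0 into (1q0, 4q1) with a constant infant share.

    ``q1 = split_fraction * q5`` and ``4q1 = 1 - (1 - q5)/(1 - q1)``, so
    that ``(1 - q1)(1 - 4q1) = 1 - q5`` exactly.
    """
    q5 = np.asarray(q5, dtype=float)
    if np.any((q5 < 0) | (q5 >= 1)):
        raise ValueError("q5 must lie in [0, 1)")
    if not (0 < split_fraction <= 1):
        raise ValueError("split_fraction must lie in (0, 1]")
    q1 = split_fraction * q5
    q4_1 = 1.0 - (1.0 - q5) / (1.0 - q1)
    if np.any((q4_1 < 0) | (q4_1 >= 1)):
        raise ValueError("implied 4q1 outside [0, 1)")
    return q1, q4_1


def q_to_m(qx, n: float, ax: float):
    """Probability of dying to central mortality rate.

    Standard life-table identity ``m = q / (n - q (n - a))`` where ``n``
    is the band width in years and ``ax`` the mean years lived in the
    band by those dying in it.
    """
    qx = np.asarray(qx, dtype=float)
    if np.any((qx < 0) | (qx >= 1)):
        raise ValueError("qx must lie in [0, 1)")
    if not (0 < ax < n):
        raise ValueError("require 0 < ax < n")
    denom = n - qx * (n - ax)
    if np.any(denom <= 0):
        raise ValueError("nonpositive life-table denominator")
    return qx / denom


def _check_years(trend: TrendEstimate, demo: pd.DataFrame):
    demo = demo.sort_values("year").reset_index(drop=True)
    years = demo["year"].to_numpy(dtype=int)
    if not np.array_equal(np.sort(np.intersect1d(years, trend.years)), years):
        missing = sorted(set(years) - set(trend.years.tolist()))
        raise ValueError(f"trend estimate does not cover demographic years {missing}")
    return demo, years


def deaths_rate_method(
    trend: TrendEstimate,
    demo: pd.DataFrame,
    split_fraction: float = 0.7,
    a0: float = 0.3,
    a1_4: float = 1.4,
) -> DeathsSeries:
    """Deaths by central rates applied to age-band populations.

    deaths(t) = m0(t) pop_age0(t) + m1-4(t) pop_age1to4(t), with rates
    derived from the trend's 5q0 via ``split_q5`` and ``q_to_m``.
    Separation-factor defaults a0 = 0.3, a1-4 = 1.4.
    """
    demo, years = _check_years(trend, demo)
    q5 = trend.at(years) / 1000.0
    q1, q4_1 = split_q5(q5, split_fraction)
    m0 = q_to_m(q1, 1.0, a0)
    m14 = q_to_m(q4_1, 4.0, a1_4)
    deaths = m0 * demo["pop_age0"].to_numpy() + m14 * demo["pop_age1to4"].to_numpy()
    return DeathsSeries(
        country_id=trend.country_id, years=years, deaths=deaths, method="rate_method"
    )


def _weekly_hazards(trend: TrendEstimate, years: np.ndarray, split_fraction: float):
    """Per-calendar-year weekly hazards for the infant and child bands."""
    q5 = trend.at(years) / 1000.0
    q1, q4_1 = split_q5(q5, split_fraction)
    h0 = -np.log1p(-q1) / WEEKS_PER_YEAR
    h1 = -np.log1p(-q4_1) / (4 * WEEKS_PER_YEAR)
    return h0, h1


def _extend_trend(trend: TrendEstimate, first: int, last: int, rule: str | None) -> TrendEstimate:
    """Extend a trend to [first, last] by holding boundary values constant."""
    missing = sorted(set(range(first, last + 1)) - set(trend.years.tolist()))
    if not missing:
        return trend
    if rule != "hold":
        raise ValueError(
            f"trend estimate missing years {missing} required for cohort follow-up"
        )
    years = np.arange(min(first, trend.years[0]), max(last, trend.years[-1]) + 1)
    r = np.interp(years.astype(float), trend.years.astype(float), trend.r_hat)
    r[years < trend.years[0]] = trend.r_hat[0]
    r[years > trend.years[-1]] = trend.r_hat[-1]
    return TrendEstimate(
        country_id=trend.country_id, years=years, r_hat=r, method=trend.method
    )


def cohort_death_allocation(
    birth_year: int,
    births: float,
    h0: np.ndarray,
    h1: np.ndarray,
    hazard_years: np.ndarray,
) -> dict[int, float]:
    """Deaths by calendar year for one yearly birth cohort.

    The cohort is split into 52 equal birth-week cohorts; each is aged
    week by week to age five under the weekly hazard of its current age
    band and calendar year, and the expected deaths of each week are
    allocated to that week's calendar year.
    """
    w = np.arange(WEEKS_PER_YEAR)  # birth week within the year
    a = np.arange(5 * WEEKS_PER_YEAR)  # age in weeks
    cal_week = w[:, None] + a[None, :]
    cal_year = birth_year + cal_week // WEEKS_PER_YEAR
    idx = np.clip(cal_year - hazard_years[0], 0, len(hazard_years) - 1)
    if cal_year.min() < hazard_years[0] or cal_year.max() > hazard_years[-1]:
        raise ValueError("hazard schedule does not cover the cohort's lifetime")
    infant = a < WEEKS_PER_YEAR
    haz = np.where(infant[None, :], h0[idx], h1[idx])
    surv_before = np.exp(-np.concatenate(
        [np.zeros((WEEKS_PER_YEAR, 1)), np.cumsum(haz, axis=1)[:, :-1]], axis=1
    ))
    weekly_deaths = (births / WEEKS_PER_YEAR) * surv_before * (1.0 - np.exp(-haz))
    out: dict[int, float] = {}
    flat_year = cal_year.ravel()
    flat_d = weekly_deaths.ravel()
    for y in np.unique(flat_year):
        out[int(y)] = float(flat_d[flat_year == y].sum())
    return out


def deaths_cohort_method(
    trend: TrendEstimate,
    demo: pd.DataFrame,
    split_fraction: float = 0.7,
    boundary_rule: str | None = "hold",
) -> DeathsSeries:
    """Deaths by birth-week cohort exposure accounting.

    deaths(t) sums contributions from all cohorts born in years t-5..t.
    Cohorts born before the first demographic year are seeded with the
    first year's births, and the period schedule outside the trend's
    span is held constant at the boundary values (``boundary_rule =
    "hold"``; pass ``None`` to require full coverage and error on
    missing years instead).
    """
    demo, years = _check_years_cohort(trend, demo)
    first, last = int(years[0]), int(years[-1])
    # cohorts born up to `last` live through last+5; lead-in cohorts need
    # the schedule back to first-5
    full = _extend_trend(trend, first - 5, last + 5, boundary_rule)
    hazard_years = np.arange(first - 5, last + 6)
    h0, h1 = _weekly_hazards(full, hazard_years, split_fraction)
    births_by_year = dict(zip(demo["year"].astype(int), demo["births"].astype(float)))
    deaths = {int(y): 0.0 for y in years}
    for birth_year in range(first - 5, last + 1):
        births = births_by_year.get(birth_year, births_by_year[first])
        alloc = cohort_death_allocation(birth_year, births, h0, h1, hazard_years)
        for y, d in alloc.items():
            if first <= y <= last:
                deaths[y] += d
    return DeathsSeries(
        country_id=trend.country_id,
        years=years,
        deaths=np.array([deaths[int(y)] for y in years]),
        method="cohort_method",
    )


def _check_years_cohort(trend: TrendEstimate, demo: pd.DataFrame):
    demo = demo.sort_values("year").reset_index(drop=True)
    years = demo["year"].to_numpy(dtype=int)
    if np.any(np.diff(years) != 1):
        raise ValueError("demographic years must be contiguous")
    return demo, years
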