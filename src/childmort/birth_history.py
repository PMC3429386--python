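"""Direct U5MR estimation from full birth histories.

Implements the synthetic-cohort life-table estimator used with DHS-style
full birth histories: within a reference period, death probabilities are
computed for the age bands 0, 1-2, 3-5, 6-11, 12-23, 24-35, 36-47 and
48-59 months from period-specific deaths and exposures, and combined
into 5q0 as one minus the product of band survival probabilities.
Standard errors come from a leave-one-woman-out jackknife.

Two period conventions are provided, matching the two estimation groups'
practice: per-survey estimates on intervals whose length grows until the
estimate's coefficient of variation is acceptable, and a pooled series
on fixed two-year intervals counting back from the latest survey (with
an optional double-counting flag on the emitted records).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OBS_COLUMNS

__all__ = [
    "AGE_BANDS_MONTHS",
    "PeriodEstimate",
    "direct_u5mr",
    "select_interval_lengths",
    "pooled_two_year_series",
    "estimates_to_observations",
]

#: band edges in months; a death at an exact edge belongs to the older band
AGE_BANDS_MONTHS = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0)


@dataclass
class PeriodEstimate:
    """5q0 for one reference period, per 1,000 live births."""

    period: tuple[float, float]
    q5_hat: float
    se: float
    n_children: int
    survey_ids: list[str] = field(default_factory=list)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.period[0] + self.period[1])

    @property
    def cv(self) -> float:
        return self.se / self.q5_hat if self.q5_hat > 0 else np.inf


def _band_contributions(bh: pd.DataFrame, period: tuple[float, float]):
    """Per-child death indicators and exposure weights for every band.

    Returns (deaths, exposure) arrays of shape (n_children, n_bands) and
    the woman index of each child.  Exposure is the fraction of the band
    the child spends inside the period while under observation; a child
    dying in a band counts as fully at risk for that band (synthetic-
    cohort convention) and its death is attributed to the period in which
    it occurred.
    """
    t0, t1 = period
    birth = bh["birth_year_decimal"].to_numpy(dtype=float)
    death_age = bh["death_age_months"].to_numpy(dtype=float)  # NaN = censored
    survey = bh["survey_year"].to_numpy(dtype=float)
    censor_age = (survey - birth) * 12.0
    died = np.isfinite(death_age)

    edges = np.asarray(AGE_BANDS_MONTHS)
    n_bands = len(edges) - 1
    deaths = np.zeros((len(bh), n_bands))
    exposure = np.zeros((len(bh), n_bands))
    # period window expressed in each child's age (months)
    p_lo = (t0 - birth) * 12.0
    p_hi = (t1 - birth) * 12.0
    for b in range(n_bands):
        s, e = edges[b], edges[b + 1]
        win_lo = np.maximum(s, p_lo)
        win_hi = np.minimum(e, p_hi)
        in_band = died & (death_age >= s) & (death_age < e)
        death_time_ok = in_band & (death_age >= p_lo) & (death_age < p_hi)
        deaths[death_time_ok, b] = 1.0
        # upper observation limit: deaths in band are fully at risk;
        # otherwise observation stops at the censoring age
        upper = np.where(in_band, win_hi, np.minimum(win_hi, censor_age))
        # children who died before the band never reach it
        upper = np.where(died & (death_age < s), win_lo, upper)
        exposure[:, b] = np.clip(upper - win_lo, 0.0, e - s) / (e - s)
    woman = bh["woman_id"].to_numpy()
    return deaths, exposure, woman


def _q5_from_totals(d: np.ndarray, e: np.ndarray, warn: bool = False) -> float:
    """1000 x (1 - prod(1 - q_band)) from band deaths/exposures."""
    q = np.zeros_like(d)
    ok = e > 0
    if warn and not ok.all():
        warnings.warn("zero exposure in some age bands; treated as q_band = 0", stacklevel=3)
    q[ok] = d[ok] / e[ok]
    q = np.clip(q, 0.0, 1.0)
    return 1000.0 * (1.0 - np.prod(1.0 - q))


def direct_u5mr(bh: pd.DataFrame, period: tuple[float, float]) -> PeriodEstimate:
    """Synthetic-cohort 5q0 for one reference period.

    ``period`` is [start, end) in decimal years.  The jackknife SE leaves
    one woman out at a time (children are clustered within women).
    """
    if period[1] <= period[0]:
        raise ValueError("period end must exceed period start")
    deaths, exposure, woman = _band_contributions(bh, period)
    tot_d = deaths.sum(axis=0)
    tot_e = exposure.sum(axis=0)
    if not (tot_e > 0).any():
        raise ValueError("zero exposure in all age bands for this period")
    q5 = _q5_from_totals(tot_d, tot_e, warn=True)

    # jackknife over women on the per-woman band totals
    wframe = pd.DataFrame(deaths).groupby(woman).sum()
    eframe = pd.DataFrame(exposure).groupby(woman).sum()
    wd = wframe.to_numpy()
    we = eframe.to_numpy()
    # only women contributing exposure in the period perturb the estimate
    contributes = we.sum(axis=1) > 0
    wd, we = wd[contributes], we[contributes]
    n_w = wd.shape[0]
    if n_w > 1:
        thetas = np.array(
            [_q5_from_totals(tot_d - wd[i], tot_e - we[i]) for i in range(n_w)]
        )
        se = float(np.sqrt((n_w - 1) / n_w * np.sum((thetas - thetas.mean()) ** 2)))
    else:
        se = np.nan
    n_children = int((exposure.sum(axis=1) > 0).sum())
    sids = sorted(set(bh["survey_year"].astype(float))) if len(bh) else []
    return PeriodEstimate(
        period=(float(period[0]), float(period[1])),
        q5_hat=float(q5),
        se=se,
        n_children=n_children,
        survey_ids=[str(s) for s in sids],
    )


def select_interval_lengths(
    bh: pd.DataFrame,
    cv_threshold: float = 0.10,
    cap: int = 5,
    recall_window: float = 15.0,
) -> list[tuple[float, float]]:
    """Data-driven period lengths, working backward from the survey date.

    Each interval grows in whole-year steps (1..cap) until the estimate's
    coefficient of variation (se / q5_hat) falls to ``cv_threshold``; if
    the threshold is never met the cap length is used with a warning.
    Intervals tile the recall window without overlap.
    """
    if cv_threshold <= 0:
        raise ValueError("cv_threshold must be positive")
    survey = float(bh["survey_year"].max())
    periods: list[tuple[float, float]] = []
    end = survey
    while end > survey - recall_window + 1e-9:
        chosen = None
        for length in range(1, cap + 1):
            start = max(end - length, survey - recall_window)
            try:
                est = direct_u5mr(bh, (start, end))
            except ValueError:
                continue
            if est.cv <= cv_threshold:
                chosen = length
                break
        if chosen is None:
            chosen = cap
            warnings.warn(
                f"CV threshold {cv_threshold} not reached at cap {cap} for interval "
                f"ending {end}; using cap length",
                stacklevel=2,
            )
        start = max(end - chosen, survey - recall_window)
        periods.append((start, end))
        end = start
    return periods


def pooled_two_year_series(
    surveys: list[pd.DataFrame],
    duplicate: bool = False,
    max_periods: int = 10,
) -> list[PeriodEstimate]:
    """Pooled direct estimates on consecutive 2-year periods.

    All birth histories are pooled (women are re-labelled per survey so
    the jackknife keeps clusters intact) and 2-year periods count back
    from the latest survey date.  With ``duplicate=True`` every estimate
    appears twice in the returned list, mirroring the double-counting of
    pooled DHS series in the downstream observation table.
    """
    if not surveys:
        raise ValueError("need at least one survey")
    parts = []
    for k, bh in enumerate(surveys):
        part = bh.copy()
        part["woman_id"] = f"s{k}:" + part["woman_id"].astype(str)
        parts.append(part)
    pooled = pd.concat(parts, ignore_index=True)
    latest = float(pooled["survey_year"].max())
    estimates: list[PeriodEstimate] = []
    for k in range(max_periods):
        period = (latest - 2.0 * (k + 1), latest - 2.0 * k)
        try:
            est = direct_u5mr(pooled, period)
        except ValueError:
            break
        estimates.append(est)
    if duplicate:
        estimates = [e for e in estimates for _ in range(2)]
    return estimates


def estimates_to_observations(
    estimates: list[PeriodEstimate],
    country_id: str,
    source_id: str,
    source_type: str = "survey_direct",
) -> pd.DataFrame:
    """Emit period estimates as observation records (ref_time = period
    midpoint).  Repeated periods are flagged as duplicates of the first
    occurrence via ``duplicate_of``."""
    rows = []
    seen: set[tuple[float, float]] = set()
    for est in estimates:
        dup = source_id if est.period in seen else None
        seen.add(est.period)
        rows.append(
            {
                "country_id": country_id,
                "ref_time": est.midpoint,
                "value_per1000": est.q5_hat,
                "source_id": source_id,
                "source_type": source_type,
                "sampling_se": est.se,
                "excluded": False,
                "duplicate_of": dup,
            }
        )
    return pd.DataFrame(rows, columns=OBS_COLUMNS)
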