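"""Comparison metrics between two sets of country estimates.

Absolute/relative difference classification grids, the annual rate of
reduction (ARR) with the MDG-4 on-track threshold, and global
aggregation of country series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "relative_difference",
    "arr",
    "mdg4_on_track",
    "DifferenceGrid",
    "difference_grid",
    "format_grid",
    "global_aggregate",
    "MDG4_THRESHOLD",
]

#: two-thirds reduction over 25 years, as an annual exponential decline (%)
MDG4_THRESHOLD = 4.4

ABS_BINS = (0.0, 10.0, 20.0, np.inf)
REL_BINS = (0.0, 10.0, 20.0, 30.0, np.inf)
ABS_LABELS = ("0-10", "10-20", "20+")
REL_LABELS = ("0-10%", "10-20%", "20-30%", "30%+")


def relative_difference(a, b, denominator: str = "max"):
    """Relative difference between two rates, in percent.

    The default denominator ``max(a, b)`` is symmetric and bounds the
    result by 100%; ``"first"`` and ``"mean"`` are available for
    alternative conventions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("rates must be positive")
    if denominator == "max":
        den = np.maximum(a, b)
    elif denominator == "first":
        den = a
    elif denominator == "mean":
        den = 0.5 * (a + b)
    else:
        raise ValueError("denominator must be 'max', 'first' or 'mean'")
    return 100.0 * np.abs(a - b) / den


def arr(r_start, r_end, years):
    """Annual rate of reduction in percent per year.

    ``100 * ln(r_start / r_end) / years``; positive when mortality
    declines.
    """
    r_start = np.asarray(r_start, dtype=float)
    r_end = np.asarray(r_end, dtype=float)
    if np.any(r_start <= 0) or np.any(r_end <= 0):
        raise ValueError("rates must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    return 100.0 * np.log(r_start / r_end) / years


def mdg4_on_track(arr_value, threshold: float = MDG4_THRESHOLD):
    """True when the ARR meets the MDG-4 pace (boundary inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return np.asarray(arr_value, dtype=float) >= threshold


@dataclass
class DifferenceGrid:
    """3x4 classification of countries by absolute and relative
    difference, with counts, 2-decimal proportions and the headline
    aggregates (abs >= 10 combined with rel >= 10% / >= 20%)."""

    year: int
    counts: pd.DataFrame  # index ABS_LABELS, columns REL_LABELS
    proportions: pd.DataFrame
    total_countries: int
    n_abs10_rel10: int
    n_abs10_rel20: int


def difference_grid(
    pairs: pd.DataFrame,
    total_countries: int | None = None,
    year: int = 0,
    denominator: str = "max",
) -> DifferenceGrid:
    """Classify per-country estimate pairs into the difference grid.

    ``pairs`` must have columns country_id, a, b (both per 1,000, one
    row per country).  Bins are left-closed/right-open; proportions are
    count over ``total_countries`` rounded to 2 decimals.
    """
    if pairs["country_id"].duplicated().any():
        dup = pairs.loc[pairs["country_id"].duplicated(), "country_id"].tolist()
        raise ValueError(f"duplicate countries {dup}")
    total = int(total_countries) if total_countries is not None else len(pairs)
    if total < len(pairs):
        raise ValueError("total_countries must be at least the number of pairs")
    a = pairs["a"].to_numpy(dtype=float)
    b = pairs["b"].to_numpy(dtype=float)
    abs_d = np.abs(a - b)
    rel_d = relative_difference(a, b, denominator)
    abs_idx = np.digitize(abs_d, ABS_BINS[1:-1], right=False)
    rel_idx = np.digitize(rel_d, REL_BINS[1:-1], right=False)
    counts = np.zeros((len(ABS_LABELS), len(REL_LABELS)), dtype=int)
    np.add.at(counts, (abs_idx, rel_idx), 1)
    counts_df = pd.DataFrame(counts, index=list(ABS_LABELS), columns=list(REL_LABELS))
    props = (counts_df / total).round(2)
    return DifferenceGrid(
        year=year,
        counts=counts_df,
        proportions=props,
        total_countries=total,
        n_abs10_rel10=int(((abs_d >= 10) & (rel_d >= 10)).sum()),
        n_abs10_rel20=int(((abs_d >= 10) & (rel_d >= 20)).sum()),
    )


def format_grid(grid: DifferenceGrid) -> str:
    """Plain-text rendering: count (proportion) per cell."""
    lines = [f"year {grid.year}  (n classified = {int(grid.counts.values.sum())}"
             f" of {grid.total_countries})"]
    header = "abs \\ rel".ljust(12) + "".join(c.rjust(14) for c in REL_LABELS)
    lines.append(header)
    for abs_label in ABS_LABELS:
        cells = []
        for rel_label in REL_LABELS:
            c = grid.counts.loc[abs_label, rel_label]
            p = grid.proportions.loc[abs_label, rel_label]
            cells.append(f"{c} ({p:.2f})".rjust(14))
        lines.append(abs_label.ljust(12) + "".join(cells))
    return "\n".join(lines)


def global_aggregate(
    country_trends: dict[str, pd.Series],
    country_births: dict[str, pd.Series],
    country_deaths: dict[str, pd.Series],
) -> pd.DataFrame:
    """Aggregate country series to the global level.

    Global deaths are the sum of country deaths; global U5MR is the
    births-weighted mean of country U5MR.  All series must share the
    same year index.
    """
    countries = list(country_trends)
    if set(country_births) != set(countries) or set(country_deaths) != set(countries):
        raise ValueError("country sets must match across inputs")
    years = None
    for cid in countries:
        idx = country_trends[cid].index
        if years is None:
            years = idx
        elif not idx.equals(years) or not country_births[cid].index.equals(years) or not country_deaths[cid].index.equals(years):
            raise ValueError(f"country {cid} missing years on the shared grid")
    u5mr = pd.DataFrame({c: country_trends[c] for c in countries})
    births = pd.DataFrame({c: country_births[c] for c in countries})
    deaths = pd.DataFrame({c: country_deaths[c] for c in countries})
    if u5mr.isna().any().any() or births.isna().any().any() or deaths.isna().any().any():
        raise ValueError("missing country-year values")
    global_u5mr = (u5mr * births).sum(axis=1) / births.sum(axis=1)
    return pd.DataFrame(
        {"year": years, "u5mr": global_u5mr.to_numpy(), "deaths": deaths.sum(axis=1).to_numpy()}
    )
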