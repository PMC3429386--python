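"""Ready-made multi-country scenario ensembles.

These helpers assemble the study conditions the estimation modules are
exercised under: each synthetic country has a log-linear (optionally
kinked) latent decline, several overlapping survey series with
heteroskedastic lognormal noise and possible systematic bias, and a gap
in the most recent years.  Two observation tables are drawn per country
— emulating two agencies' partially overlapping databases assembled
from the same underlying reality — so the difference decomposition has
realistic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ScenarioConfig, SourceSpec, TrueTrajectory
from .synthetic import generate_observations, generate_trajectory

__all__ = ["CountryData", "survey_only_country", "survey_only_ensemble"]

DEFAULT_YEAR_RANGE = (1990, 2010)
#: sampling CVs by source type: direct survey series are noisier than VR
DEFAULT_CV = {"survey_direct": 0.05, "survey_indirect": 0.08}


@dataclass
class CountryData:
    """One synthetic country: truth plus the two agencies' tables."""

    country_id: str
    truth: TrueTrajectory
    igme_records: pd.DataFrame
    ihme_records: pd.DataFrame
    meta: dict


def _random_sources(rng: np.random.Generator, year_range) -> list[SourceSpec]:
    """Survey-only source landscape: 2-4 direct series plus one indirect."""
    y0, y1 = year_range
    sources = []
    n_direct = int(rng.integers(2, 5))
    for k in range(n_direct):
        survey_year = int(rng.integers(y0 + 8, y1))
        span = int(rng.integers(8, 15))
        years = range(max(y0, survey_year - span), survey_year)
        bias = float(np.exp(rng.normal(0.0, 0.03)))
        sources.append(
            SourceSpec(
                source_id=f"DHS-{survey_year}-{k}",
                source_type="survey_direct",
                bias_factor=bias,
                sampling_cv=DEFAULT_CV["survey_direct"],
                years_covered=list(years),
                survey_year=survey_year,
            )
        )
    survey_year = int(rng.integers(y0 + 5, y1 - 2))
    sources.append(
        SourceSpec(
            source_id=f"CENSUS-{survey_year}",
            source_type="survey_indirect",
            bias_factor=float(np.exp(rng.normal(0.0, 0.05))),
            sampling_cv=DEFAULT_CV["survey_indirect"],
            years_covered=list(range(max(y0, survey_year - 10), survey_year - 2)),
            survey_year=survey_year,
        )
    )
    return sources


def survey_only_country(
    country_id: str,
    seed: int,
    year_range=DEFAULT_YEAR_RANGE,
    births_per_year: float = 100_000.0,
) -> CountryData:
    """One survey-only country with two overlapping observation tables.

    The latent 5q0 declines log-linearly from a level drawn in
    (30, 250) per 1,000 at an annual rate drawn in (1%, 6%).  The two
    tables share most sources; each agency additionally misses or adds
    a series, which is what drives the data component downstream.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = year_range
    level0 = float(np.exp(rng.uniform(np.log(0.03), np.log(0.25))))
    arr = rng.uniform(0.01, 0.06)
    level1 = level0 * np.exp(-arr * (y1 - y0))
    config = ScenarioConfig(
        country_id=country_id,
        year_range=year_range,
        trend_knots=[(y0, np.log10(level0)), (y1, np.log10(level1))],
        sources=_random_sources(rng, year_range),
        births_per_year=births_per_year,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    truth = generate_trajectory(config)
    all_sources = list(config.sources)
    # each agency drops (at most) one distinct series from the shared pool
    n = len(all_sources)
    drop_igme = int(rng.integers(0, n)) if n > 3 else None
    drop_ihme = int(rng.integers(0, n)) if n > 3 else None
    if drop_igme == drop_ihme:
        drop_ihme = None
    # realize every source once so that series shared by both agencies
    # carry identical values, then subset per agency
    full = generate_observations(truth, all_sources, seed=config.seed)
    igme_ids = {s.source_id for i, s in enumerate(all_sources) if i != drop_igme}
    ihme_ids = {s.source_id for i, s in enumerate(all_sources) if i != drop_ihme}
    igme = full[full["source_id"].isin(igme_ids)].reset_index(drop=True)
    ihme_own = full[full["source_id"].isin(ihme_ids)].reset_index(drop=True)
    meta = {
        "source_types": sorted({s.source_type for s in all_sources}),
        "high_hiv": False,
        "standard_procedure": True,
        "true_arr": 100.0 * arr,
    }
    return CountryData(
        country_id=country_id,
        truth=truth,
        igme_records=igme,
        ihme_records=ihme_own,
        meta=meta,
    )


def survey_only_ensemble(
    n_countries: int,
    seed: int,
    year_range=DEFAULT_YEAR_RANGE,
) -> list[CountryData]:
    """Independent survey-only countries (one child seed each)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_countries)
    return [
        survey_only_country(f"C{i:03d}", int(child.generate_state(1)[0] % (2**31 - 1)), year_range)
        for i, child in enumerate(children)
    ]
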