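"""End-to-end pipeline: simulate, fit, convert to deaths, decompose,
compare — with every output CSV carrying the config hash and seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import TrendEstimate
from .deaths import deaths_cohort_method, deaths_rate_method
from .decomposition import decompose_deaths, decompose_u5mr, summarize_decomposition
from .gpr import GPRConfig
from .io import config_hash, write_csv
from .loess import default_alpha
from .metrics import arr, difference_grid, global_aggregate, mdg4_on_track
from .scenarios import survey_only_ensemble

log = logging.getLogger("childmort")

STAGES = ("simulate", "fit-loess", "fit-gpr", "deaths", "decompose", "compare")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-mappable)."""

    out_dir: str = "out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_countries: int = 12
    year_range: tuple[int, int] = (1990, 2010)
    alpha: float | None = None  # None: per-country data-driven default
    gpr: GPRConfig = field(default_factory=GPRConfig)
    split_fraction: float = 0.7
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.n_countries < 1:
            raise ValueError("n_countries must be positive")

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "n_countries": self.n_countries,
            "year_range": list(self.year_range),
            "alpha": self.alpha,
            "gpr": vars(self.gpr),
            "split_fraction": self.split_fraction,
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns a bundle of in-memory artifacts and writes one CSV per
    artifact under ``config.out_dir``.  Idempotent for a fixed config:
    all randomness flows from ``config.seed``.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    meta = {"config_hash": config_hash(config.as_dict()), "seed": config.seed}
    bundle: dict = {"meta": meta}

    countries = survey_only_ensemble(config.n_countries, config.seed, config.year_range)
    bundle["countries"] = countries
    years = np.arange(config.year_range[0], config.year_range[1] + 1)

    if "simulate" in config.stages:
        obs = pd.concat(
            [c.igme_records.assign(agency="igme") for c in countries]
            + [c.ihme_records.assign(agency="ihme") for c in countries],
            ignore_index=True,
        )
        demo = pd.concat([c.truth.demographics() for c in countries], ignore_index=True)
        write_csv(obs, out / "observations.csv", meta)
        write_csv(demo, out / "demographics.csv", meta)
        bundle["observations"] = obs
        bundle["demographics"] = demo
        log.info("simulated %d countries", len(countries))
    if not ({"fit-loess", "fit-gpr", "deaths", "decompose", "compare"} & set(config.stages)):
        return bundle

    decomps = []
    loess_trends: dict[str, TrendEstimate] = {}
    gpr_trends: dict[str, TrendEstimate] = {}
    deaths_rows = []
    for c in countries:
        alpha = config.alpha if config.alpha is not None else default_alpha(c.igme_records)
        res = decompose_u5mr(
            c.igme_records,
            c.ihme_records,
            alpha,
            years,
            gpr_config=GPRConfig(**{**vars(config.gpr), "seed": config.seed}),
            country_id=c.country_id,
        )
        r_igme, r_ihme = res.r_igme, res.r_ihme
        loess_trends[c.country_id] = r_igme
        gpr_trends[c.country_id] = r_ihme
        demo = c.truth.demographics()
        if "deaths" in config.stages or "decompose" in config.stages or "compare" in config.stages:
            d_rate = deaths_rate_method(r_igme, demo, config.split_fraction)
            d_cohort = deaths_cohort_method(r_ihme, demo, config.split_fraction)
            deaths_rows.append(d_rate.to_frame())
            deaths_rows.append(d_cohort.to_frame())
            dd = decompose_deaths(r_igme, r_ihme, demo, years, config.split_fraction)
            res.table = res.table.merge(dd, on="year")
        decomps.append(res)

    if "fit-loess" in config.stages:
        write_csv(pd.concat([t.to_frame() for t in loess_trends.values()]), out / "trend_loess.csv", meta)
    if "fit-gpr" in config.stages:
        write_csv(pd.concat([t.to_frame() for t in gpr_trends.values()]), out / "trend_gpr.csv", meta)
    if "deaths" in config.stages and deaths_rows:
        write_csv(pd.concat(deaths_rows, ignore_index=True), out / "deaths.csv", meta)
    bundle["decompositions"] = decomps
    bundle["loess_trends"] = loess_trends
    bundle["gpr_trends"] = gpr_trends

    if "decompose" in config.stages:
        per_country = pd.concat(
            [r.table.assign(country_id=r.country_id) for r in decomps], ignore_index=True
        )
        write_csv(per_country, out / "decomposition.csv", meta)
        summary_years = [y for y in (1990, 2000, 2010) if y in years] or [int(years[-1])]
        summary = summarize_decomposition(decomps, summary_years)
        write_csv(summary, out / "decomposition_summary.csv", meta)
        bundle["decomposition_summary"] = summary

    if "compare" in config.stages:
        y_cmp = int(years[-1])
        pairs = pd.DataFrame(
            {
                "country_id": [c.country_id for c in countries],
                "a": [loess_trends[c.country_id].at([y_cmp])[0] for c in countries],
                "b": [gpr_trends[c.country_id].at([y_cmp])[0] for c in countries],
            }
        )
        grid = difference_grid(pairs, year=y_cmp)
        write_csv(grid.counts.reset_index(names="abs_diff"), out / f"grid_{y_cmp}.csv", meta)
        arr_tbl = pd.DataFrame(
            {
                "country_id": [c.country_id for c in countries],
                "arr_loess": [
                    arr(loess_trends[c.country_id].at([years[0]])[0],
                        loess_trends[c.country_id].at([years[-1]])[0],
                        int(years[-1] - years[0]))
                    for c in countries
                ],
                "arr_gpr": [
                    arr(gpr_trends[c.country_id].at([years[0]])[0],
                        gpr_trends[c.country_id].at([years[-1]])[0],
                        int(years[-1] - years[0]))
                    for c in countries
                ],
            }
        )
        arr_tbl["on_track_loess"] = mdg4_on_track(arr_tbl["arr_loess"])
        arr_tbl["on_track_gpr"] = mdg4_on_track(arr_tbl["arr_gpr"])
        write_csv(arr_tbl, out / "arr.csv", meta)
        trends = {c.country_id: pd.Series(loess_trends[c.country_id].r_hat, index=years) for c in countries}
        births = {c.country_id: pd.Series(c.truth.births, index=years) for c in countries}
        dmap = {
            c.country_id: pd.Series(
                deaths_rate_method(loess_trends[c.country_id], c.truth.demographics(), config.split_fraction).deaths,
                index=years,
            )
            for c in countries
        }
        global_tbl = global_aggregate(trends, births, dmap)
        write_csv(global_tbl, out / "global.csv", meta)
        bundle["grid"] = grid
        bundle["arr"] = arr_tbl
        bundle["global"] = global_tbl
    return bundle
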