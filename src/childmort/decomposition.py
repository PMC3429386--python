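"""Decomposition of inter-agency U5MR and deaths differences.

The total difference between a loess fit to one group's data (R_igme)
and a GP fit to the other group's data (R_ihme) splits exactly into a
data-driven and a method-driven component through the bridging loess
fit to the second group's data (R_tilde):

    delta_R        = R_igme - R_ihme
    delta_R_data   = R_igme - R_tilde      (same method, different data)
    delta_R_method = R_tilde - R_ihme      (same data, different method)

and delta_R = delta_R_data + delta_R_method identically.  Both loess
fits must use the same span so that the data term reflects data alone.
The deaths decomposition is analogous, bridging through the rate-based
deaths method applied to the second trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import TrendEstimate
from .deaths import deaths_cohort_method, deaths_rate_method
from .gpr import GPRConfig, BiasModel, VarianceModel, fit_gpr, fit_prior_mean
from .loess import LoessConfig, fit_loess

__all__ = [
    "DecompositionResult",
    "eligible_for_decomposition",
    "decompose_u5mr",
    "decompose_deaths",
    "summarize_decomposition",
]


@dataclass
class DecompositionResult:
    """Per-year decomposition for one country.

    U5MR components are per 1,000 live births; deaths components are
    counts.  Deaths columns are NaN until ``decompose_deaths`` fills
    them.
    """

    country_id: str
    table: pd.DataFrame  # year, delta_R, delta_R_data, delta_R_method, [deaths cols]
    r_igme: TrendEstimate | None = None
    r_tilde: TrendEstimate | None = None
    r_ihme: TrendEstimate | None = None

    def __post_init__(self):
        need = {"year", "delta_R", "delta_R_data", "delta_R_method"}
        if not need <= set(self.table.columns):
            raise ValueError(f"decomposition table missing columns {sorted(need - set(self.table.columns))}")


def eligible_for_decomposition(country_meta: dict) -> bool:
    """Country-selection filter for the trend decomposition.

    Eligible countries have no vital-registration series, are not
    flagged as high-HIV-prevalence, and were estimated with the standard
    procedure — so that the decomposition isolates the fitting machinery
    from bias adjustments and expert interventions.
    """
    for key in ("source_types", "high_hiv", "standard_procedure"):
        if key not in country_meta:
            raise ValueError(f"country metadata missing {key!r}")
    has_vr = any(t.startswith("vr") for t in country_meta["source_types"])
    return (not has_vr) and (not country_meta["high_hiv"]) and bool(country_meta["standard_procedure"])


def _apply_cutoff(records: pd.DataFrame, cutoff_year: float | None) -> pd.DataFrame:
    """Drop records *collected* after the cutoff (survey-date proxy:
    ref_time), mirroring the exclusion of post-2009 collections when the
    comparison database froze in 2010."""
    if cutoff_year is None:
        return records
    return records[records["ref_time"] <= cutoff_year]


def decompose_u5mr(
    igme_records: pd.DataFrame,
    ihme_records: pd.DataFrame,
    alpha: float,
    years,
    gpr_config: GPRConfig | None = None,
    var_model: VarianceModel | None = None,
    bias_model: BiasModel | None = None,
    cutoff_year: float | None = None,
    country_id: str | None = None,
    prior_spans=None,
) -> DecompositionResult:
    """Three-fit decomposition of the U5MR difference on a year grid.

    Fits loess (span ``alpha``) to both record sets — the same span in
    both fits, so the data term is not confounded by smoothing — and the
    GP to the second set, then returns the per-year differences.
    """
    years = np.asarray(list(years), dtype=int)
    if len(igme_records) == 0 or len(ihme_records) == 0:
        raise ValueError("both record sets must be nonempty")
    igme_records = _apply_cutoff(igme_records, cutoff_year)
    ihme_records = _apply_cutoff(ihme_records, cutoff_year)
    cfg = LoessConfig(alpha=alpha)
    r_igme = fit_loess(igme_records, cfg, years, country_id=country_id)
    r_tilde = fit_loess(ihme_records, cfg, years, country_id=country_id)
    gpr_config = gpr_config or GPRConfig()
    if prior_spans is not None:
        prior, _ = fit_prior_mean(ihme_records, candidate_spans=prior_spans)
    else:
        prior, _ = fit_prior_mean(ihme_records)
    r_ihme, _, _ = fit_gpr(
        ihme_records,
        prior.predict_scale,
        gpr_config,
        var_model or VarianceModel(),
        bias_model,
        predict_years=years,
        country_id=country_id,
    )
    table = pd.DataFrame(
        {
            "year": years,
            "delta_R": r_igme.r_hat - r_ihme.r_hat,
            "delta_R_data": r_igme.r_hat - r_tilde.r_hat,
            "delta_R_method": r_tilde.r_hat - r_ihme.r_hat,
        }
    )
    cid = country_id or r_igme.country_id
    return DecompositionResult(
        country_id=cid, table=table, r_igme=r_igme, r_tilde=r_tilde, r_ihme=r_ihme
    )


def decompose_deaths(
    r_igme: TrendEstimate,
    r_ihme: TrendEstimate,
    demo: pd.DataFrame,
    years,
    split_fraction: float = 0.7,
    bridge: str = "rate_on_ihme",
) -> pd.DataFrame:
    """Decompose the deaths difference into rate-driven and
    method-driven components.

    Default bridging order ("rate_on_ihme") evaluates the rate effect
    under the rate-based deaths method:

        delta_D_rate   = rate(r_igme) - rate(r_ihme)
        delta_D_method = rate(r_ihme) - cohort(r_ihme)

    The symmetric alternative ("cohort_on_igme") evaluates the method
    effect on the first trend instead.  Either way the two components
    sum exactly to delta_D = rate(r_igme) - cohort(r_ihme).
    """
    years = np.asarray(list(years), dtype=int)
    demo_y = demo[demo["year"].isin(years)]
    if sorted(demo_y["year"]) != sorted(years.tolist()):
        raise ValueError("demographic inputs missing requested years")
    d_rate_igme = deaths_rate_method(r_igme, demo_y, split_fraction).deaths
    d_cohort_ihme = deaths_cohort_method(r_ihme, demo_y, split_fraction).deaths
    if bridge == "rate_on_ihme":
        mid = deaths_rate_method(r_ihme, demo_y, split_fraction).deaths
        d_rate = d_rate_igme - mid
        d_method = mid - d_cohort_ihme
    elif bridge == "cohort_on_igme":
        mid = deaths_cohort_method(r_igme, demo_y, split_fraction).deaths
        d_rate = mid - d_cohort_ihme
        d_method = d_rate_igme - mid
    else:
        raise ValueError("bridge must be 'rate_on_ihme' or 'cohort_on_igme'")
    return pd.DataFrame(
        {
            "year": years,
            "delta_D": d_rate_igme - d_cohort_ihme,
            "delta_D_rate": d_rate,
            "delta_D_method": d_method,
        }
    )


def summarize_decomposition(
    results: list[DecompositionResult],
    years,
    components: tuple[str, ...] = ("delta_R_data", "delta_R_method"),
) -> pd.DataFrame:
    """Across-country mean (SD) of each component at each year.

    Returns a table with one row per component and one ``"m (s)"``
    formatted column per year, alongside numeric mean/sd columns.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 countries to summarize (SD undefined)")
    years = [int(y) for y in years]
    rows = []
    for comp in components:
        row: dict = {"component": comp}
        for y in years:
            vals = []
            for res in results:
                sub = res.table[res.table["year"] == y]
                if len(sub) != 1:
                    raise ValueError(f"country {res.country_id} missing year {y}")
                vals.append(float(sub[comp].iloc[0]))
            vals = np.array(vals)
            mean, sd = vals.mean(), vals.std(ddof=1)
            row[f"mean_{y}"] = mean
            row[f"sd_{y}"] = sd
            row[str(y)] = f"{mean:.1f} ({sd:.1f})"
        rows.append(row)
    return pd.DataFrame(rows)
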