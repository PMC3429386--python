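import numpy as np
import pandas as pd
import pytest

from childmort import (
    ScenarioConfig,
    SourceSpec,
    generate_observations,
    generate_trajectory,
)


def make_config(country_id="X", q5_start=0.1, q5_end=0.05, year_range=(1990, 2010),
                sources=(), seed=0, **kw):
    y0, y1 = year_range
    return ScenarioConfig(
        country_id=country_id,
        year_range=year_range,
        trend_knots=[(y0, np.log10(q5_start)), (y1, np.log10(q5_end))],
        sources=list(sources),
        seed=seed,
        **kw,
    )


@pytest.fixture
def declining_trajectory():
    """Log-linear decline from 100 to 50 per 1,000 over 1990-2010."""
    return generate_trajectory(make_config())


@pytest.fixture
def noisefree_observations(declining_trajectory):
    """One unbiased noise-free yearly series over 1990-2005."""
    spec = SourceSpec("S", "survey_direct", 1.0, 0.0, range(1990, 2006), survey_year=2006)
    return generate_observations(declining_trajectory, [spec], seed=0)


@pytest.fixture
def noisy_observations(declining_trajectory):
    """Two overlapping direct series with 5% sampling CV."""
    specs = [
        SourceSpec("A", "survey_direct", 1.0, 0.05, range(1990, 2004), survey_year=2004),
        SourceSpec("B", "survey_direct", 1.0, 0.05, range(1995, 2008), survey_year=2008),
    ]
    return generate_observations(declining_trajectory, specs, seed=42)


def toy_birth_histories(death_ages_months, survey_year=2010.0, birth_year=2000.0):
    """One child per woman, all born at the same time; death ages given in
    months (None = survives past the survey)."""
    rows = []
    for i, age in enumerate(death_ages_months):
        rows.append(
            {
                "woman_id": f"w{i}",
                "child_id": f"w{i}c0",
                "birth_year_decimal": birth_year,
                "death_age_months": np.nan if age is None else float(age),
                "survey_year": survey_year,
            }
        )
    return pd.DataFrame(rows)
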