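# Methods

This note documents the statistical machinery implemented in
`childmort`: the two trend-fitting methods for the under-five mortality
rate (U5MR, the probability 5q0 that a newborn dies before exact age
five, reported per 1,000 live births), direct estimation from full
birth histories, the two under-five-deaths estimators, the exact
decomposition of differences between two sets of estimates, and the
synthetic data the pipeline is exercised on.

## The estimation problem

National U5MR series must be assembled from heterogeneous, partially
overlapping data sources: complete or incomplete vital registration
(VR), direct estimates from full birth histories (DHS-style surveys),
and indirect estimates from summary birth histories. Observations carry
sampling error (heteroskedastic, roughly proportional to the level) and
non-sampling error, and individual series can be systematically biased
— incomplete VR under-records child deaths. Trend-fitting turns this
scatter into a comparable yearly series per country. Two estimation
traditions coexist: a loess smoother fit to a curated database, and
Gaussian-process regression (GPR) with an explicit observation-variance
model fit to a more inclusive database. This package implements both,
plus the bookkeeping needed to say *why* their outputs differ.

## Scales and conventions

All trend fitting happens on log10(U5MR per 1,000). The log scale keeps
back-transformed estimates positive, makes multiplicative biases
additive, and makes a constant annual rate of reduction (ARR) a straight
line. Sampling standard errors are mapped to the log10 scale by the
delta method: `se_log10 = se / (value · ln 10)`.

## Loess trend (`childmort.loess`)

`LoessTrend` is a scikit-learn-style estimator performing locally
weighted linear regression of log10 U5MR on time with a tricube kernel.
The span `alpha` is the fraction of points entering each local window
when ≤ 1 (minimum window of 2 points); for `alpha > 1` every point
enters with the kernel distance scale inflated by `alpha`, so the fit
tends to a single global weighted line as `alpha → ∞`. Predictions
beyond the data range use the local line fitted at the nearest boundary
point (linear extrapolation on the log scale) — extrapolation behaviour
must be pinned down because recent years frequently have no data and
the decomposition compares extrapolations across methods.

`default_alpha` supplies a data-driven span: 1.0 below 20 usable
points, 0.7 from 20–99, 0.5 at 100 or more. The step table is
configurable and is constrained to be non-increasing in data volume;
the specific constants are package defaults, chosen so countries with
sparse survey data get a stiff fit and VR-rich countries a flexible
one.

`fit_loess_with_bias` co-estimates one multiplicative bias factor per
flagged series (the incomplete-VR case) by alternating (i) a loess fit
to bias-corrected data and (ii) setting each flagged series' log10 bias
to its mean residual about the current fit, to a 1e-6 change tolerance
(at most 100 iterations). With at least one unflagged series the factor
is identified; with only flagged series the routine refuses. On
noise-free data a known factor of 0.8 is recovered to well under 1e-4.

Degenerate local designs (all window points at one time) fall back to a
weighted mean with a warning. Excluded records never enter any fit.

## Gaussian-process trend (`childmort.gpr`)

`GPTrend` performs exact Gaussian conditioning on the log10 scale:

* **Prior mean** — a loess curve whose span is chosen by leave-one-out
  cross-validation over a candidate list (default 0.3, 0.5, 0.7, 1.0,
  2.0), minimizing squared prediction error on the log scale; ties
  break to the largest (smoothest) span.
* **Covariance** — Matérn with smoothness 3/2 (`amplitude²(1 + √3·dt/ℓ)
  exp(−√3·dt/ℓ)`), defaults amplitude 0.1 (log10 units) and length
  scale 10 years; smoothness 1/2 and 5/2 are available. The default
  smoothness gives once-differentiable trajectories — smooth enough for
  a mortality trend, rough enough to follow decade-scale accelerations.
  `tune_hyperparameters` optionally picks (amplitude, length scale) on
  a small grid by closed-form leave-one-out predictive density.
* **Observation variance** — per record, the sum of its delta-method
  sampling variance and a source-type non-sampling variance.
  `estimate_nonsampling_variance` pools log10 residuals about
  first-pass (loess) fits across countries and attributes the excess
  over mean sampling variance to non-sampling error, floored at zero;
  source types with fewer than 5 residuals fall back to the pooled
  all-type value.
* **VR bias** — flagged series share one additive log10 bias parameter
  with a Gaussian prior (a "regional" prior mean and SD). The parameter
  is integrated out analytically: the marginal data covariance gains a
  rank-one term `s0²hhᵀ` (h the flag indicator), and the bias posterior
  is read off the same linear-Gaussian system. With unflagged series
  present, a noise-free log10 bias of −0.1 is recovered to under 1e-3;
  with VR only, the posterior shrinks to the prior mean.

The fitted trend is summarized by `n_trajectories` (default 1,000)
seeded posterior draws on the prediction grid: the point estimate is
the per-year median of the draws (quantile-consistent under the
back-transform, unlike the mean) and the bounds are the 2.5/97.5
percentiles. Cholesky factorization escalates jitter from 1e-10 to at
most 1e-6 before declaring the covariance non-positive-definite.

Calibration: over 200 simulated survey-only countries with correctly
specified sampling noise, the pooled empirical coverage of the 95%
intervals is ≈ 97% (the acceptance suite requires 90–99%).

## Direct estimation from birth histories (`childmort.birth_history`)

The synthetic-cohort life-table estimator uses the standard DHS age
bands 0, 1–2, 3–5, 6–11, 12–23, 24–35, 36–47, 48–59 months (deaths at
an exact boundary belong to the older band). Within a reference period,
each band's death probability is deaths over exposure, where a child's
exposure is the fraction of the band it spends inside the period while
under observation; a child dying in a band counts as fully at risk for
that band and its death is attributed to the period containing the
death. 5q0 is one minus the product of band survivals, per 1,000.
Standard errors are leave-one-woman-out jackknife (children cluster
within mothers). Bands with zero exposure are skipped with a warning;
zero exposure everywhere is an error.

Two period conventions are provided. `select_interval_lengths` works
backward from the survey date, growing each interval in whole-year
steps (cap 5) until the estimate's coefficient of variation reaches a
threshold (default 0.10) — the cap is used, with a warning, if the
threshold is never met. `pooled_two_year_series` pools all surveys of a
country (women relabelled per survey so the jackknife keeps clusters
intact) and estimates on consecutive 2-year intervals counting back
from the latest survey; an optional flag emits every estimate twice,
with the duplicates marked, mirroring the double-counting convention of
pooled series in one of the two databases emulated.

## Deaths estimation (`childmort.deaths`)

5q0 is split into infant and child components with a constant infant
share: `q1 = f·q5` (default f = 0.7) and `4q1 = 1 − (1−q5)/(1−q1)`, so
survival composes exactly. The split fraction is a free parameter of
the synthetic world; nothing downstream assumes a particular value.

* **Rate method** — the life-table identity `m = q/(n − q(n − a))`
  converts band probabilities to central death rates with separation
  factors a0 = 0.3 years (band 0, n = 1) and a1–4 = 1.4 years (band
  1–4, n = 4), common life-table practice for high-to-moderate
  mortality populations; yearly deaths are `m0·pop0 + m1–4·pop1–4`.
* **Cohort method** — each yearly birth cohort is split into 52 equal
  birth-week cohorts (a 52-week year convention) and aged week by week
  to age five under piecewise-constant weekly hazards derived from the
  period schedule; the hazard switches at calendar-year boundaries and
  at age one, and each week's expected deaths accrue to that week's
  calendar year. The schedule outside the fitted range is held constant
  at the boundary values (5 lead years for cohorts already alive at the
  start, 5 trailing years for follow-up); passing `boundary_rule=None`
  instead raises an error naming the missing years.

The cohort method conserves deaths exactly: a cohort's allocated deaths
over all years equal size × (1 − survival to five) computed from the
same hazards, to floating-point precision. Under a time-constant
schedule with a consistent stationary population the two methods agree
within 2% (the residual is the separation-factor approximation); under
changing mortality they differ by construction, which is precisely the
method component of the deaths decomposition. An event-level
microsimulation (piecewise-constant hazard inversion per child) agrees
with the deterministic allocation within Monte Carlo error at 10⁶
children.

## Decomposition (`childmort.decomposition`)

For a year grid, with loess fit `R_igme` to the first dataset, loess
fit `R̃` to the second dataset at the *same* span, and GP fit `R_ihme`
to the second dataset:

    ΔR        = R_igme − R_ihme
    ΔR^(d)    = R_igme − R̃        (data component)
    ΔR^(m)    = R̃ − R_ihme       (method component)

The identity ΔR = ΔR^(d) + ΔR^(m) holds exactly (it is a telescoping
sum); the tests enforce 1e-9. Using one span for both loess fits is a
contract, not a convenience — otherwise the data term confounds
smoothing differences. An optional cutoff year drops records collected
after it before fitting, for comparisons against a database frozen
earlier. The eligibility filter restricts the exercise to survey-only,
non-high-HIV, standard-procedure countries so that bias adjustments and
expert interventions do not contaminate the comparison.

The deaths decomposition bridges through the rate method applied to the
second trend (`delta_D_rate = rate(r_igme) − rate(r_ihme)`,
`delta_D_method = rate(r_ihme) − cohort(r_ihme)`); the symmetric
bridging order is available behind a flag, and either order sums
exactly to the total. Summaries report the across-country mean and
sample SD per component per year, formatted "m (s)".

## Comparison metrics (`childmort.metrics`)

Relative differences default to the symmetric denominator `max(a, b)`
(bounded by 100% and invariant to swapping the two agencies); `first`
and `mean` denominators are selectable. The classification grid bins
countries by absolute difference ([0,10), [10,20), [20,∞) per 1,000)
crossed with relative difference ([0,10), [10,20), [20,30), [30,∞) %),
left-closed/right-open, with proportions rounded to two decimals, and
reports the headline aggregates (abs ≥ 10 crossed with rel ≥ 10% and
≥ 20%). ARR between two years is `100·ln(r_start/r_end)/years`; the
MDG-4 on-track test compares it (boundary inclusive) against 4.4%/year,
the pace equivalent to a two-thirds reduction over 25 years
(100·ln 3/25 ≈ 4.39). Global aggregates are the sum of country deaths
and the births-weighted mean of country U5MR.

## Synthetic data (`childmort.synthetic`, `childmort.scenarios`)

The generator emulates the multi-source country data landscape:

* latent 5q0 is the exponential of a piecewise-linear log10 trend,
  optionally multiplied by a conflict spike over a few years;
* observations are `1000 · q5 · bias_factor · exp(ε)` with
  ε ~ N(0, cv²) — lognormal noise keeps values positive and matches the
  log-scale fitting convention — and `sampling_se = value · cv`;
* full birth histories arise from Poisson fertility over a reproductive
  window, with child deaths simulated by inverting the two-band
  (0–1, 1–5) piecewise-constant hazards consistent with each period's
  q1/q5, right-censored at the survey date;
* demographic counts are the stationary person-years implied by each
  year's schedule (constant yearly births by default).

Data-preparation rules mirror curation practice: a single multiplicative
completeness adjustment applied to an entire VR series (e.g. 10% or
20% upward), and an exclusion rule flagging a series that is below
every other series wherever it overlaps (overlap window ±1 year — the
convention this package fixes, since "overlap" is otherwise ambiguous;
a series with no overlap anywhere is left unflagged with a warning).

`survey_only_ensemble` draws independent countries with 2–4 direct
survey series plus one indirect series, mild lognormal source biases
(log SD 0.03–0.05), sampling CVs of 5–8%, and data gaps in the most
recent years; two observation tables are emitted per country, sharing
most sources but each missing a series the other has, so the
decomposition's data term is non-trivial. Default study sizes: 12
countries in the pipeline demo, 36 in the decomposition exercise, 200
scenarios for interval calibration, 10⁶ children for the
microsimulation oracle.

What the synthetic world deliberately lacks: HIV-driven selection bias
in birth histories, recall and displacement errors in reported death
ages, census-quality heterogeneity, and migration. Passing tests
therefore establish internal correctness and calibration under the
stated error model, not performance on real survey microdata.

## Numerical choices and edge cases

* Loess windows of fewer than 2 points are impossible by construction;
  singular local designs fall back to weighted means with warnings.
* GP covariance jitter escalates 1e-10 → 1e-6 before failure.
* Bias iteration tolerance 1e-6 on the log10 factor, 100 iterations.
* Cross-validation ties break toward the largest span.
* Grid bin edges are left-closed/right-open; the MDG-4 boundary is
  inclusive.
* Deaths at exact age-band boundaries belong to the older band.
* All stochastic components accept explicit seeds; fixed seeds give
  bit-identical tables, fits and posterior draws.

## Known limitations

The loess span defaults and the GPR hyperparameter grid are package
choices, configurable but not estimated from any real database. The
indirect-series generator applies a bias model directly rather than
emulating summary-birth-history computation. The pooled 2-year series
recall depth (10 periods) and the interval-selection recall window (15
years) are conventions. Real inter-agency comparisons involve
databases this package does not ship; the pipeline demonstrates the
machinery on synthetic countries only.
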