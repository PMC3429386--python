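"""Gaussian-process trend estimation: Matérn covariance, exact
conditioning, variance estimation, prior-mean cross-validation, and the
analytic VR-bias parameter."""

import numpy as np
import pandas as pd
import pytest
from sklearn.gaussian_process.kernels import Matern as SkMatern

from childmort import (
    BiasModel,
    GPRConfig,
    GPTrend,
    VarianceModel,
    estimate_nonsampling_variance,
    estimate_vr_bias,
    fit_gpr,
    fit_loess,
    fit_prior_mean,
    generate_observations,
    generate_trajectory,
    matern_cov,
    tune_hyperparameters,
)
from childmort.datatypes import SourceSpec
from childmort.loess import LoessConfig
from conftest import make_config
from test_loess import obs_table


class TestMaternCov:
    def test_zero_lag_is_amplitude_squared(self):
        assert matern_cov(0.0, 2.0, 5.0) == pytest.approx(4.0)

    def test_decays_to_zero(self):
        assert matern_cov(1e4, 1.0, 2.0) < 1e-10

    def test_closed_form_value(self):
        # amplitude 1, l = 2, dt = 2: (1 + sqrt(3)) exp(-sqrt(3))
        expected = (1 + np.sqrt(3)) * np.exp(-np.sqrt(3))
        assert matern_cov(2.0, 1.0, 2.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("nu", [0.5, 1.5, 2.5])
    def test_matches_sklearn_matern(self, nu):
        dts = np.array([0.1, 1.0, 3.0, 7.5])
        k = SkMatern(length_scale=4.0, nu=nu)
        theirs = k(np.zeros((1, 1)), dts.reshape(-1, 1)).ravel()
        ours = matern_cov(dts, 1.0, 4.0, nu=nu)
        assert np.allclose(ours, theirs, rtol=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            matern_cov(1.0, -1.0, 2.0)
        with pytest.raises(ValueError):
            matern_cov(1.0, 1.0, 0.0)


class TestGPConditioning:
    def test_noise_free_interpolation_of_single_point(self):
        est = GPTrend(amplitude=0.1, length_scale=10.0).fit(
            np.array([2000.0]), np.array([2.0]), noise_var=np.array([0.0])
        )
        assert est.predict(np.array([2000.0]))[0] == pytest.approx(2.0, abs=1e-8)

    def test_infinite_noise_returns_prior_mean(self):
        mean = lambda t: 1.5 - 0.01 * (t - 2000)
        est = GPTrend(amplitude=0.1, length_scale=10.0, prior_mean=mean).fit(
            np.array([1995.0, 2005.0]),
            np.array([5.0, -3.0]),
            noise_var=np.array([1e12, 1e12]),
        )
        grid = np.array([1990.0, 2000.0, 2010.0])
        assert np.allclose(est.predict(grid), mean(grid), atol=1e-6)

    def test_two_point_posterior_matches_hand_conditioning(self):
        x = np.array([1998.0, 2004.0])
        y = np.array([2.0, 1.8])
        nv = np.array([0.01, 0.02])
        amp, ls = 0.3, 6.0
        est = GPTrend(amplitude=amp, length_scale=ls).fit(x, y, noise_var=nv)
        xq = 2001.0
        got = est.predict(np.array([xq]))[0]
        # hand-coded 2x2 Gaussian conditioning
        K = matern_cov(np.abs(x[:, None] - x[None, :]), amp, ls) + np.diag(nv)
        ks = matern_cov(np.abs(x - xq), amp, ls)
        expected = ks @ np.linalg.solve(K, y)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_posterior_variance_never_exceeds_prior_variance(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(1990, 2010, 12))
        y = rng.normal(2.0, 0.1, 12)
        est = GPTrend(amplitude=0.2, length_scale=8.0).fit(
            x, y, noise_var=np.full(12, 0.005)
        )
        _, sd = est.predict(np.arange(1985.0, 2016.0), return_std=True)
        assert np.all(sd <= 0.2 + 1e-9)

    def test_order_and_duplication_equivalence(self):
        x = np.array([1995.0, 2000.0, 2005.0])
        y = np.array([2.0, 1.9, 1.7])
        nv = np.array([0.01, 0.02, 0.01])
        grid = np.arange(1990.0, 2011.0)
        base = GPTrend().fit(x, y, noise_var=nv).predict(grid)
        perm = [2, 0, 1]
        permuted = GPTrend().fit(x[perm], y[perm], noise_var=nv[perm]).predict(grid)
        assert np.allclose(base, permuted, atol=1e-10)
        # one record at variance v equals two copies at variance 2v
        x2 = np.array([1995.0, 2000.0, 2000.0, 2005.0])
        y2 = np.array([2.0, 1.9, 1.9, 1.7])
        nv2 = np.array([0.01, 0.04, 0.04, 0.01])
        doubled = GPTrend().fit(x2, y2, noise_var=nv2).predict(grid)
        assert np.allclose(base, doubled, atol=1e-10)

    def test_seeded_trajectory_draws_reproducible(self):
        x = np.array([1995.0, 2005.0])
        y = np.array([2.0, 1.8])
        est = GPTrend().fit(x, y, noise_var=np.array([0.01, 0.01]))
        grid = np.arange(1990.0, 2011.0)
        a = est.sample_trajectories(grid, 50, random_state=123)
        b = est.sample_trajectories(grid, 50, random_state=123)
        assert np.array_equal(a, b)


class TestPriorMean:
    def test_linear_noise_free_ties_break_to_largest_span(self):
        years = np.arange(1990, 2010)
        values = 100.0 * 10 ** (-0.02 * (years - 1990))
        _, span = fit_prior_mean(obs_table(years, values), candidate_spans=(0.5, 0.8, 1.2))
        assert span == 1.2

    def test_single_candidate_returned(self):
        years = np.arange(1990, 2000)
        values = 100.0 * 10 ** (-0.02 * (years - 1990))
        _, span = fit_prior_mean(obs_table(years, values), candidate_spans=(0.6,))
        assert span == 0.6

    def test_wiggly_data_selects_smaller_span_than_its_linearization(self):
        rng = np.random.default_rng(1)
        years = np.arange(1985.0, 2011.0)
        wiggle = 2.0 - 0.01 * (years - 2000) + 0.15 * np.sin((years - 1985) / 2.0)
        noise = rng.normal(0, 0.01, len(years))
        spans = (0.3, 0.5, 0.8, 1.2)
        _, span_wiggly = fit_prior_mean(obs_table(years, 10 ** (wiggle + noise)), spans)
        linear = 2.0 - 0.01 * (years - 2000)
        _, span_linear = fit_prior_mean(obs_table(years, 10 ** (linear + noise)), spans)
        assert span_wiggly <= span_linear

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_prior_mean(obs_table([2000, 2001, 2002], [50, 50, 50]))


class TestNonsamplingVariance:
    def _records(self, extra_sd, seed, n_countries=4):
        out, fits = {}, {}
        for c in range(n_countries):
            traj = generate_trajectory(make_config(country_id=f"C{c}", seed=c))
            specs = [
                SourceSpec("A", "survey_direct", 1.0, 0.05, range(1990, 2011), survey_year=2011),
                SourceSpec("B", "survey_direct", 1.0, 0.05, range(1990, 2011), survey_year=2011),
            ]
            obs = generate_observations(traj, specs, seed=seed + c)
            if extra_sd > 0:
                rng = np.random.default_rng(seed + 100 + c)
                obs["value_per1000"] *= np.exp(
                    rng.normal(0, extra_sd * np.log(10), len(obs))
                )
            out[f"C{c}"] = obs
            fits[f"C{c}"] = fit_loess(obs, LoessConfig(0.7), traj.years)
        return out, fits

    def test_sampling_only_data_gives_near_zero(self):
        recs, fits = self._records(extra_sd=0.0, seed=0)
        vm = estimate_nonsampling_variance(recs, fits)
        assert vm.variance("survey_direct") < 1e-3

    def test_recovers_injected_source_level_variance(self):
        # extra log10 SD of 0.1 -> variance 0.01, recovered within 30%
        # averaged over replicates
        vals = []
        for rep in range(100):
            recs, fits = self._records(extra_sd=0.1, seed=rep * 7, n_countries=2)
            vm = estimate_nonsampling_variance(recs, fits)
            vals.append(vm.variance("survey_direct"))
        assert abs(np.mean(vals) - 0.01) < 0.003

    def test_single_source_type_gives_single_entry(self):
        recs, fits = self._records(extra_sd=0.0, seed=3)
        vm = estimate_nonsampling_variance(recs, fits)
        assert set(vm.by_type) == {"survey_direct"}

    def test_sparse_type_falls_back_to_pooled(self):
        recs, fits = self._records(extra_sd=0.0, seed=5)
        # make two records of a rare type
        first = next(iter(recs))
        recs[first] = recs[first].copy()
        recs[first].loc[:1, "source_type"] = "vr_complete"
        with pytest.warns(UserWarning, match="pooled"):
            vm = estimate_nonsampling_variance(recs, fits)
        assert vm.variance("vr_complete") == pytest.approx(vm.default)


class TestVrBias:
    def _setup(self, bias_log10=-0.1, with_survey=True):
        traj = generate_trajectory(make_config())
        specs = [SourceSpec("VR", "vr_incomplete", 10.0**bias_log10, 0.0, range(1990, 2011))]
        if with_survey:
            specs.append(
                SourceSpec("S", "survey_direct", 1.0, 0.0, range(1990, 2008), survey_year=2008)
            )
        obs = generate_observations(traj, specs, seed=0)
        prior, _ = fit_prior_mean(obs[obs["source_id"] != "VR"] if with_survey else obs)
        return obs, prior

    def test_recovers_known_log10_bias(self):
        obs, prior = self._setup(bias_log10=-0.1)
        mean, sd = estimate_vr_bias(
            obs,
            prior.predict_scale,
            GPRConfig(amplitude=0.1, length_scale=10.0),
            VarianceModel(default=1e-6),
            BiasModel(sources={"VR"}, prior_mean=0.0, prior_sd=1.0),
        )
        assert mean == pytest.approx(-0.1, abs=1e-3)

    def test_unbiased_vr_gives_near_zero(self):
        obs, prior = self._setup(bias_log10=0.0)
        mean, _ = estimate_vr_bias(
            obs,
            prior.predict_scale,
            GPRConfig(),
            VarianceModel(default=1e-6),
            BiasModel(sources={"VR"}, prior_mean=0.0, prior_sd=1.0),
        )
        assert abs(mean) < 1e-3

    def test_vr_only_shrinks_to_regional_prior(self):
        obs, prior = self._setup(bias_log10=-0.1, with_survey=False)
        mean, sd = estimate_vr_bias(
            obs,
            prior.predict_scale,
            GPRConfig(),
            VarianceModel(default=1e-6),
            BiasModel(sources={"VR"}, prior_mean=-0.05, prior_sd=1e-4),
        )
        assert mean == pytest.approx(-0.05, abs=1e-3)


class TestFitGpr:
    def test_posterior_median_tracks_noise_free_data(self):
        traj = generate_trajectory(make_config())
        spec = SourceSpec("S", "survey_direct", 1.0, 0.0, range(1990, 2011), survey_year=2011)
        obs = generate_observations(traj, [spec], seed=0)
        prior, _ = fit_prior_mean(obs)
        trend, draws, _ = fit_gpr(
            obs, prior.predict_scale, GPRConfig(seed=3, n_trajectories=2000), VarianceModel()
        )
        assert np.allclose(trend.r_hat, 1000 * traj.q5, rtol=0.01)
        assert draws.shape == (2000, 21)
        assert np.all(trend.lower <= trend.r_hat) and np.all(trend.r_hat <= trend.upper)

    def test_tune_hyperparameters_returns_grid_member(self):
        traj = generate_trajectory(make_config())
        spec = SourceSpec("S", "survey_direct", 1.0, 0.05, range(1990, 2011), survey_year=2011)
        obs = generate_observations(traj, [spec], seed=1)
        prior, _ = fit_prior_mean(obs)
        amp, ls = tune_hyperparameters(
            obs, prior.predict_scale, VarianceModel(), (0.05, 0.1), (5.0, 10.0)
        )
        assert amp in (0.05, 0.1) and ls in (5.0, 10.0)
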