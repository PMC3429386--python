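"""Gaussian-process trend fitting for U5MR series (IHME style).

The log10 U5MR trajectory is modelled as a Gaussian process whose mean
is a loess curve (span chosen by leave-one-out cross-validation) and
whose covariance is a Matérn function of the time lag.  Each
observation's noise variance is the sum of its sampling variance and a
source-type-specific non-sampling variance, both on the log10 scale.
Series flagged as biased (incomplete vital registration) carry an
additive log10 bias parameter with a Gaussian prior; the parameter is
integrated out analytically, so the posterior over trajectories and the
bias posterior are exact linear-Gaussian conditioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import TrendEstimate, active_observations
from .loess import LoessTrend, loess_smooth

__all__ = [
    "matern_cov",
    "GPTrend",
    "GPRConfig",
    "VarianceModel",
    "BiasModel",
    "fit_prior_mean",
    "estimate_nonsampling_variance",
    "fit_gpr",
    "estimate_vr_bias",
    "tune_hyperparameters",
]

LN10 = np.log(10.0)


def matern_cov(dt, amplitude: float, length_scale: float, nu: float = 1.5):
    """Matérn covariance of the time lag ``dt`` (years).

    For smoothness nu = 3/2:
    ``amplitude^2 (1 + sqrt(3) dt / l) exp(-sqrt(3) dt / l)``.
    Smoothness 1/2 (exponential) and 5/2 are also supported.
    """
    if amplitude <= 0 or length_scale <= 0:
        raise ValueError("amplitude and length_scale must be positive")
    dt = np.abs(np.asarray(dt, dtype=float))
    if np.any(dt < 0):
        raise ValueError("dt must be nonnegative")
    a2 = amplitude**2
    if nu == 0.5:
        return a2 * np.exp(-dt / length_scale)
    if nu == 1.5:
        s = np.sqrt(3.0) * dt / length_scale
        return a2 * (1.0 + s) * np.exp(-s)
    if nu == 2.5:
        s = np.sqrt(5.0) * dt / length_scale
        return a2 * (1.0 + s + s**2 / 3.0) * np.exp(-s)
    raise ValueError("supported smoothness values: 0.5, 1.5, 2.5")


@dataclass
class VarianceModel:
    """Non-sampling variance per source type, on the log10 scale."""

    by_type: dict[str, float] = field(default_factory=dict)
    default: float = 0.0

    def __post_init__(self):
        if self.default < 0 or any(v < 0 for v in self.by_type.values()):
            raise ValueError("non-sampling variances must be nonnegative")

    def variance(self, source_type: str) -> float:
        return self.by_type.get(source_type, self.default)


@dataclass
class BiasModel:
    """Additive log10 bias prior for flagged VR series.

    ``prior_mean`` below zero encodes expected under-reporting; the prior
    SD controls how much the data can move the bias estimate (a diffuse
    prior requires unflagged series for identification).
    """

    sources: set = field(default_factory=set)
    prior_mean: float = 0.0
    prior_sd: float = 0.1

    def __post_init__(self):
        if self.prior_sd <= 0:
            raise ValueError("bias prior SD must be positive")


@dataclass
class GPRConfig:
    """Covariance and sampling settings for the GP trend fit."""

    matern_smoothness: float = 1.5
    amplitude: float = 0.1
    length_scale: float = 10.0
    n_trajectories: int = 1000
    seed: int = 0
    jitter: float = 1e-10

    def __post_init__(self):
        if self.amplitude <= 0 or self.length_scale <= 0:
            raise ValueError("amplitude and length_scale must be positive")


class GPTrend(RegressorMixin, BaseEstimator):
    """Exact GP regression on the log10 scale with heteroskedastic noise
    and an optional shared additive bias parameter.

    Parameters
    ----------
    amplitude, length_scale, nu : Matérn covariance parameters (log10
        scale / years).
    prior_mean : callable or None
        Function of time returning the prior mean on the log10 scale;
        ``None`` uses a zero mean.

    Fit parameters (``fit`` keyword arguments)
    ------------------------------------------
    noise_var : per-record noise variance on the log10 scale.
    bias_mask : boolean mask of records carrying the shared bias.
    bias_prior : (mean, sd) of the Gaussian bias prior.

    Attributes
    ----------
    bias_mean_, bias_sd_ : posterior of the bias parameter (when a mask
        was supplied).
    """

    def __init__(
        self,
        amplitude: float = 0.1,
        length_scale: float = 10.0,
        nu: float = 1.5,
        prior_mean=None,
        jitter: float = 1e-10,
    ):
        self.amplitude = amplitude
        self.length_scale = length_scale
        self.nu = nu
        self.prior_mean = prior_mean
        self.jitter = jitter

    def _mean(self, x):
        if self.prior_mean is None:
            return np.zeros(len(x))
        return np.asarray(self.prior_mean(np.asarray(x, float)), dtype=float)

    def _kernel(self, xa, xb):
        return matern_cov(
            np.subtract.outer(np.asarray(xa, float), np.asarray(xb, float)),
            self.amplitude,
            self.length_scale,
            self.nu,
        )

    def fit(self, X, y, noise_var=None, bias_mask=None, bias_prior=(0.0, 0.1)):
        x = np.asarray(X, dtype=float).reshape(len(y), -1)[:, 0]
        y = np.asarray(y, dtype=float)
        if len(x) == 0:
            raise ValueError("records nonempty required")
        nv = np.zeros(len(x)) if noise_var is None else np.asarray(noise_var, dtype=float)
        if nv.shape != x.shape:
            raise ValueError("noise_var must align with observations")
        if np.any(nv < 0):
            raise ValueError("noise variances must be nonnegative")
        self.x_ = x
        self.y_ = y
        self.noise_var_ = nv
        self.n_features_in_ = 1
        h = np.zeros(len(x)) if bias_mask is None else np.asarray(bias_mask, dtype=float)
        b0, s0 = bias_prior
        # marginal covariance of the observations with the bias integrated out
        C = self._kernel(x, x) + np.diag(nv) + (s0**2) * np.outer(h, h)
        resid = y - self._mean(x) - b0 * h
        self._chol_ = self._robust_cholesky(C)
        self._alpha_ = linalg.cho_solve((self._chol_, True), resid)
        self._h_ = h
        self._bias_prior_ = (float(b0), float(s0))
        if bias_mask is not None and h.any():
            Cih = linalg.cho_solve((self._chol_, True), h)
            self.bias_mean_ = float(b0 + s0**2 * resid @ Cih)
            var_b = s0**2 - s0**4 * h @ Cih
            self.bias_sd_ = float(np.sqrt(max(var_b, 0.0)))
        else:
            self.bias_mean_ = None
            self.bias_sd_ = None
        return self

    def _robust_cholesky(self, C):
        eye = np.eye(C.shape[0])
        for jitter in [0.0] + [self.jitter * 10**k for k in range(12)]:
            if jitter > 1e-6:
                break
            try:
                return linalg.cholesky(C + jitter * eye, lower=True)
            except linalg.LinAlgError:
                continue
        raise linalg.LinAlgError(
            "covariance matrix not positive definite after jitter escalation to 1e-6"
        )

    def predict(self, X, return_std: bool = False, return_cov: bool = False):
        check_is_fitted(self, "x_")
        xq = np.asarray(X, dtype=float).reshape(-1)
        Ks = self._kernel(xq, self.x_)
        mean = self._mean(xq) + Ks @ self._alpha_
        if not (return_std or return_cov):
            return mean
        V = linalg.cho_solve((self._chol_, True), Ks.T)
        cov = self._kernel(xq, xq) - Ks @ V
        # bias uncertainty does not propagate to the latent trajectory:
        # the trajectory covariance already conditions on data through C
        if return_cov:
            return mean, cov
        return mean, np.sqrt(np.clip(np.diag(cov), 0.0, None))

    def sample_trajectories(self, X, n: int, random_state=None) -> np.ndarray:
        """Draw posterior trajectories (log10 scale), shape (n, len(X))."""
        mean, cov = self.predict(X, return_cov=True)
        rng = np.random.default_rng(random_state)
        cov = cov + 1e-12 * np.eye(len(mean))
        L = linalg.cholesky(cov + 0.0, lower=True)
        z = rng.standard_normal((n, len(mean)))
        return mean[None, :] + z @ L.T


def fit_prior_mean(
    records: pd.DataFrame,
    candidate_spans=(0.3, 0.5, 0.7, 1.0, 2.0),
) -> tuple[LoessTrend, float]:
    """Choose the prior-mean loess span by leave-one-out cross-validation.

    Squared prediction error is evaluated on the log10 scale; ties are
    broken toward the largest (smoothest) span.  Returns the loess
    estimator fitted on all records at the chosen span.
    """
    active = active_observations(records)
    if len(active) < 5:
        raise ValueError("need at least 5 records to cross-validate the prior mean")
    x = active["ref_time"].to_numpy(dtype=float)
    z = np.log10(active["value_per1000"].to_numpy(dtype=float))
    n = len(x)
    best = None
    for span in candidate_spans:
        try:
            errs = np.empty(n)
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                pred = loess_smooth(x[mask], z[mask], x[i : i + 1], span)[0]
                errs[i] = (pred - z[i]) ** 2
            mse = float(np.mean(errs))
        except Exception:
            continue
        # strict improvement required, so ties resolve to the largest span
        if best is None or mse < best[0] - 1e-15 or (abs(mse - best[0]) <= 1e-15 and span > best[1]):
            best = (mse, span)
    if best is None:
        raise ValueError("all candidate spans failed")
    span = best[1]
    est = LoessTrend(alpha=span).fit(x, active["value_per1000"].to_numpy())
    return est, span


def _sampling_var_log10(values: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Delta-method sampling variance on the log10 scale."""
    return (np.asarray(se, float) / (np.asarray(values, float) * LN10)) ** 2


def estimate_nonsampling_variance(
    multi_country_records: dict[str, pd.DataFrame],
    trend_fits: dict[str, TrendEstimate],
    min_residuals: int = 5,
) -> VarianceModel:
    """Pool log10 residuals about first-pass fits across countries and
    attribute the excess over sampling variance to non-sampling error.

    For each source type: ``max(0, var(residuals) - mean sampling
    variance)``.  Types with fewer than ``min_residuals`` residuals fall
    back to the pooled all-type value (with a warning).
    """
    if len(multi_country_records) < 2:
        raise ValueError("need records from at least 2 countries")
    frames = []
    for cid, recs in multi_country_records.items():
        active = active_observations(recs)
        trend = trend_fits[cid]
        fit_z = np.interp(
            active["ref_time"].to_numpy(dtype=float),
            trend.years.astype(float),
            np.log10(trend.r_hat),
        )
        resid = np.log10(active["value_per1000"].to_numpy(dtype=float)) - fit_z
        frames.append(
            pd.DataFrame(
                {
                    "source_type": active["source_type"].to_numpy(),
                    "resid": resid,
                    "samp_var": _sampling_var_log10(
                        active["value_per1000"].to_numpy(), active["sampling_se"].to_numpy()
                    ),
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    pooled_value = max(0.0, float(pooled["resid"].var(ddof=1)) - float(pooled["samp_var"].mean()))
    by_type = {}
    for stype, grp in pooled.groupby("source_type"):
        if len(grp) < min_residuals:
            warnings.warn(
                f"source type {stype!r} has {len(grp)} residuals (<{min_residuals}); "
                "using pooled all-type non-sampling variance",
                stacklevel=2,
            )
            by_type[stype] = pooled_value
        else:
            by_type[stype] = max(
                0.0, float(grp["resid"].var(ddof=1)) - float(grp["samp_var"].mean())
            )
    return VarianceModel(by_type=by_type, default=pooled_value)


def _prepare_gpr_inputs(records: pd.DataFrame, var_model: VarianceModel, bias_model: BiasModel | None):
    active = active_observations(records)
    if len(active) == 0:
        raise ValueError("records nonempty required")
    x = active["ref_time"].to_numpy(dtype=float)
    v = active["value_per1000"].to_numpy(dtype=float)
    z = np.log10(v)
    noise = _sampling_var_log10(v, active["sampling_se"].to_numpy()) + np.array(
        [var_model.variance(t) for t in active["source_type"]]
    )
    if bias_model is not None and bias_model.sources:
        mask = active["source_id"].isin(bias_model.sources).to_numpy()
    else:
        mask = None
    return active, x, z, noise, mask


def fit_gpr(
    records: pd.DataFrame,
    prior_mean,
    config: GPRConfig,
    var_model: VarianceModel | None = None,
    bias_model: BiasModel | None = None,
    predict_years=None,
    country_id: str | None = None,
) -> tuple[TrendEstimate, np.ndarray, GPTrend]:
    """Fit the GP trend and summarize it by posterior trajectory draws.

    ``prior_mean`` is a callable on decimal years returning log10 values
    (e.g. ``fit_prior_mean(...)[0].predict_scale``).  Returns the trend
    estimate (posterior median with 2.5/97.5 percentile bounds, per
    1,000), the matrix of log10 posterior draws, and the fitted
    estimator.  Draws are seeded via ``config.seed``.
    """
    var_model = var_model or VarianceModel()
    active, x, z, noise, mask = _prepare_gpr_inputs(records, var_model, bias_model)
    if predict_years is None:
        predict_years = np.arange(int(np.floor(x.min())), int(np.ceil(x.max())) + 1)
    predict_years = np.asarray(list(predict_years), dtype=int)
    bias_prior = (bias_model.prior_mean, bias_model.prior_sd) if bias_model else (0.0, 0.1)
    est = GPTrend(
        amplitude=config.amplitude,
        length_scale=config.length_scale,
        nu=config.matern_smoothness,
        prior_mean=prior_mean,
        jitter=config.jitter,
    ).fit(x, z, noise_var=noise, bias_mask=mask, bias_prior=bias_prior)
    draws = est.sample_trajectories(predict_years.astype(float), config.n_trajectories, config.seed)
    med = np.median(draws, axis=0)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    cid = country_id if country_id is not None else str(active["country_id"].iloc[0])
    trend = TrendEstimate(
        country_id=cid,
        years=predict_years,
        r_hat=10.0**med,
        method="gpr",
        scale_value=med,
        lower=10.0**lo,
        upper=10.0**hi,
    )
    return trend, draws, est


def estimate_vr_bias(
    records: pd.DataFrame,
    prior_mean,
    config: GPRConfig,
    var_model: VarianceModel,
    bias_model: BiasModel,
) -> tuple[float, float]:
    """Posterior mean and SD of the shared log10 VR bias parameter.

    With unflagged series present the bias is identified by the data
    (flagged VR is pulled toward the level set by the other sources);
    with flagged VR only, the posterior shrinks to the regional prior.
    """
    _, _, _, _, mask = _prepare_gpr_inputs(records, var_model, bias_model)
    if mask is None or not mask.any():
        raise ValueError("no records belong to a flagged bias source")
    _, _, est = fit_gpr(records, prior_mean, config, var_model, bias_model)
    return est.bias_mean_, est.bias_sd_


def tune_hyperparameters(
    records: pd.DataFrame,
    prior_mean,
    var_model: VarianceModel,
    amplitude_grid=(0.02, 0.05, 0.1, 0.2),
    length_scale_grid=(5.0, 10.0, 20.0),
    nu: float = 1.5,
) -> tuple[float, float]:
    """Pick (amplitude, length_scale) by leave-one-out predictive density.

    Uses the closed-form Gaussian LOO identities on the marginal
    covariance; returns the grid point with the highest summed log
    predictive density.
    """
    active, x, z, noise, _ = _prepare_gpr_inputs(records, var_model, None)
    m = prior_mean(x) if prior_mean is not None else np.zeros(len(x))
    resid = z - m
    best = None
    for amp in amplitude_grid:
        for ls in length_scale_grid:
            C = matern_cov(np.subtract.outer(x, x), amp, ls, nu) + np.diag(noise)
            try:
                Ci = linalg.inv(C + 1e-10 * np.eye(len(x)))
            except linalg.LinAlgError:
                continue
            ci_diag = np.diag(Ci)
            mu_loo = z - (Ci @ resid) / ci_diag
            var_loo = 1.0 / ci_diag
            lpd = float(
                np.sum(-0.5 * np.log(2 * np.pi * var_loo) - 0.5 * (z - mu_loo) ** 2 / var_loo)
            )
            if best is None or lpd > best[0]:
                best = (lpd, amp, ls)
    if best is None:
        raise ValueError("no grid point produced a valid covariance")
    return best[1], best[2]
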