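"""Loess trend fitting for U5MR series (UN IGME style).

The trend is a locally weighted linear regression of log10(U5MR per
1,000) on time.  A span parameter ``alpha`` sets the size of each local
window (the fraction of points entering each local fit when <= 1) and a
tricube kernel sets their weights.  Predictions outside the data range
extend the boundary local line (linear extrapolation).

An iterative variant co-estimates a multiplicative bias factor for
series flagged as systematically biased (e.g. incomplete vital
registration): the fit and the per-source mean log-residual are
alternated to convergence.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import TrendEstimate, active_observations

__all__ = ["LoessTrend", "default_alpha", "fit_loess", "fit_loess_with_bias", "LoessConfig"]


class LoessConfig:
    """Bag of loess settings: span, scale and flagged-bias sources."""

    def __init__(self, alpha: float = 0.7, bias_sources: set | None = None):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = alpha
        self.bias_sources = set(bias_sources or ())


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_smooth(
    x: np.ndarray, y: np.ndarray, x_new: np.ndarray, alpha: float
) -> np.ndarray:
    """Evaluate the loess fit of (x, y) at x_new.

    For alpha <= 1 each local window holds ceil(alpha*n) nearest points
    (minimum 2); for alpha > 1 all points enter with the kernel distance
    scale inflated by alpha.  Queries beyond the data range are evaluated
    on the local line fitted at the nearest boundary point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two points")
    lo, hi = x.min(), x.max()
    out = np.empty(len(x_new))
    for i, xq in enumerate(np.asarray(x_new, dtype=float)):
        x0 = min(max(xq, lo), hi)  # anchor extrapolation at the boundary
        d = np.abs(x - x0)
        if alpha <= 1.0:
            k = min(n, max(2, math.ceil(alpha * n)))
            h = np.partition(d, k - 1)[k - 1]
        else:
            h = d.max() * alpha
        if h <= 0:
            h = 1.0  # all window points coincide; weights become equal
        w = _tricube(d / h)
        # local line through x0, evaluated at the query point
        active = w > 0
        xa, ya, wa = x[active], y[active], w[active]
        xc = xa - x0
        sw = wa.sum()
        mx = (wa * xc).sum() / sw
        sxx = (wa * (xc - mx) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, (wa * xc**2).sum() + 1.0):
            warnings.warn("singular local design; falling back to weighted mean", stacklevel=2)
            out[i] = (wa * ya).sum() / sw
            continue
        my = (wa * ya).sum() / sw
        slope = (wa * (xc - mx) * (ya - my)).sum() / sxx
        intercept = my - slope * mx
        out[i] = intercept + slope * (xq - x0)
    return out


class LoessTrend(RegressorMixin, BaseEstimator):
    """Locally weighted linear regression of log10(U5MR) on time.

    Parameters
    ----------
    alpha : float
        Span: fraction of points in each local window when <= 1;
        values > 1 inflate the kernel distance scale so the fit tends to
        a single global weighted line as alpha grows.
    transform : {"log10", "identity"}
        Scale on which the local fits are performed.  U5MR fitting uses
        log10 so that back-transformed estimates stay positive.

    Attributes
    ----------
    x_ : ndarray — training times (sorted)
    z_ : ndarray — training response on the transform scale
    n_features_in_ : int
    """

    def __init__(self, alpha: float = 0.7, transform: str = "log10"):
        self.alpha = alpha
        self.transform = transform

    def _to_scale(self, y):
        return np.log10(y) if self.transform == "log10" else np.asarray(y, float)

    def _from_scale(self, z):
        return 10.0**z if self.transform == "log10" else z

    def fit(self, X, y):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        x = np.asarray(X, dtype=float).reshape(len(y), -1)[:, 0]
        y = np.asarray(y, dtype=float)
        if len(x) < 3:
            raise ValueError("need at least 3 observations to fit a loess trend")
        if self.transform == "log10" and np.any(y <= 0):
            raise ValueError("log10 transform requires positive values")
        order = np.argsort(x, kind="stable")
        self.x_ = x[order]
        self.z_ = self._to_scale(y)[order]
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "x_")
        xq = np.asarray(X, dtype=float).reshape(-1)
        z = loess_smooth(self.x_, self.z_, xq, self.alpha)
        return self._from_scale(z)

    def predict_scale(self, X):
        """Prediction on the transform (log10) scale."""
        check_is_fitted(self, "x_")
        xq = np.asarray(X, dtype=float).reshape(-1)
        return loess_smooth(self.x_, self.z_, xq, self.alpha)


def default_alpha(
    records: pd.DataFrame,
    table: tuple[tuple[int, float], ...] = ((20, 1.0), (100, 0.7)),
    floor: float = 0.5,
) -> float:
    """Default span from the amount of data available.

    A monotone non-increasing step function of the number of non-excluded
    points: with ``table = ((20, 1.0), (100, 0.7))`` the span is 1.0 below
    20 points, 0.7 from 20 to 99, and ``floor`` (0.5) at 100 or more.
    The mapping is configurable; richer data always yields an equal or
    smaller span.
    """
    active = active_observations(records)
    n = len(active)
    if n < 3:
        raise ValueError("insufficient data: need at least 3 non-excluded records")
    alphas = [a for _, a in table] + [floor]
    if any(b < a for a, b in zip(alphas[1:], alphas[:-1])) and alphas != sorted(alphas, reverse=True):
        raise ValueError("alpha table must be non-increasing")
    for threshold, alpha in table:
        if n < threshold:
            return alpha
    return floor


def fit_loess(
    records: pd.DataFrame,
    config: LoessConfig,
    predict_years,
    country_id: str | None = None,
) -> TrendEstimate:
    """Fit the loess trend to an observation table.

    Excluded records never enter the fit.  Returns yearly point estimates
    per 1,000 on the requested (contiguous) prediction years.
    """
    predict_years = np.asarray(list(predict_years), dtype=int)
    if len(predict_years) == 0:
        raise ValueError("predict_years must be nonempty")
    active = active_observations(records)
    if len(active) < 3:
        raise ValueError("insufficient data: need at least 3 non-excluded records")
    est = LoessTrend(alpha=config.alpha).fit(
        active["ref_time"].to_numpy(), active["value_per1000"].to_numpy()
    )
    z = est.predict_scale(predict_years.astype(float))
    cid = country_id if country_id is not None else str(active["country_id"].iloc[0])
    return TrendEstimate(
        country_id=cid,
        years=predict_years,
        r_hat=10.0**z,
        method="loess",
        scale_value=z,
    )


def fit_loess_with_bias(
    records: pd.DataFrame,
    config: LoessConfig,
    predict_years,
    tol: float = 1e-6,
    max_iter: int = 100,
    country_id: str | None = None,
) -> tuple[TrendEstimate, dict[str, float]]:
    """Loess fit with multiplicative bias factors for flagged series.

    Alternates between (i) a loess fit to bias-corrected data and (ii)
    setting each flagged source's log10 bias to its mean residual about
    the current fit, until the largest bias change is below ``tol``.
    Returns the final fit and the multiplicative bias factor per flagged
    source (a factor of 0.8 means the series under-reports by 20%).
    """
    if not config.bias_sources:
        return fit_loess(records, config, predict_years, country_id), {}
    active = active_observations(records).reset_index(drop=True)
    flagged = active["source_id"].isin(config.bias_sources).to_numpy()
    if flagged.all():
        raise ValueError("bias unidentifiable: every record belongs to a flagged source")
    if not flagged.any():
        return fit_loess(records, config, predict_years, country_id), {}
    x = active["ref_time"].to_numpy(dtype=float)
    z = np.log10(active["value_per1000"].to_numpy(dtype=float))
    src = active["source_id"].to_numpy()
    bias = {s: 0.0 for s in config.bias_sources if (src == s).any()}
    for _ in range(max_iter):
        z_adj = z.copy()
        for s, b in bias.items():
            z_adj[src == s] -= b
        fit_z = loess_smooth(x, z_adj, x, config.alpha)
        delta = 0.0
        for s in bias:
            m = src == s
            new_b = float(np.mean(z[m] - fit_z[m]))
            delta = max(delta, abs(new_b - bias[s]))
            bias[s] = new_b
        if delta < tol:
            break
    z_adj = z.copy()
    for s, b in bias.items():
        z_adj[src == s] -= b
    predict_years = np.asarray(list(predict_years), dtype=int)
    z_hat = loess_smooth(x, z_adj, predict_years.astype(float), config.alpha)
    cid = country_id if country_id is not None else str(active["country_id"].iloc[0])
    trend = TrendEstimate(
        country_id=cid, years=predict_years, r_hat=10.0**z_hat, method="loess", scale_value=z_hat
    )
    return trend, {s: 10.0**b for s, b in bias.items()}
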