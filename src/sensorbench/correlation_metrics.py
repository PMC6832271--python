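"""Correlation battery: R-squared, lagged cross-correlation with stationarity
handling, MIC, the MIC - R^2 nonlinearity classification and k-means
clustering of pair profiles.

R^2 (squared Pearson correlation, identically the OLS coefficient of
determination) quantifies the linear association of a channel pair on the
original scale.  Lead/lag between devices is estimated from the per-lag
Pearson correlation of the (differenced-to-stationarity) series over integer
second lags -15..+15.  MIC captures any functional association, so the score
``MIC - R^2`` separates "false" linear (< -eps), "true" linear (|.| <= eps)
and nonlinear-functional (> eps) relationships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.tsa.stattools import adfuller

from ._mine import mic_score
from .signal_prep import ParameterSeries

logger = logging.getLogger(__name__)

MAX_DIFFERENCING = 2
MIN_OVERLAP = 30
CLUSTER_LEVELS = ("low", "moderate", "high")


def _values(x) -> np.ndarray:
    return np.asarray(x.v if isinstance(x, ParameterSeries) else x, dtype=float)


def _resolution_ms(x, default: float = 1000.0) -> float:
    if isinstance(x, ParameterSeries) and len(x) >= 2:
        return x.resolution_ms
    return default


@dataclass(frozen=True)
class MICConfig:
    """MINE search parameters: grid bound ``B(n) = n**alpha``, clump factor
    ``c`` and the sample size up to which the grid search is exhaustive."""

    alpha: float = 0.6
    c: float = 15.0
    exact_n: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.c < 1:
            raise ValueError("c must be >= 1")


@dataclass
class CrossCorrelation:
    """Per-lag Pearson correlation of a (possibly differenced) pair.

    A positive ``best_lag`` means the second series lags behind the first
    (the first, reference series is leading).
    """

    lags: np.ndarray  # seconds
    coefficients: np.ndarray  # Pearson r per lag, NaN where skipped
    best_lag: float  # seconds, argmax of the coefficients
    differenced: int  # order of differencing applied

    @property
    def peak(self) -> float:
        return float(np.nanmax(self.coefficients))


@dataclass(frozen=True)
class AssociationClass:
    """Nonlinearity verdict from the score MIC - R^2 against +/- epsilon."""

    value: str  # false_linear | true_linear | nonlinear_functional
    score: float
    epsilon: float


def linear_r2(x, y) -> float:
    """Squared Pearson correlation == R^2 of the OLS fit of y on x."""
    xv, yv = _values(x), _values(y)
    if xv.size != yv.size:
        raise ValueError("series must have equal length")
    if xv.size < 3:
        raise ValueError("need length >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        logger.warning("linear_r2: zero-variance input, returning NaN")
        return float("nan")
    r = stats.pearsonr(xv, yv).statistic
    return float(r * r)


def adf_stationary(x, alpha: float = 0.05) -> tuple[bool, float]:
    """Augmented Dickey-Fuller unit-root test with AIC lag selection.

    Returns (stationary, p-value); stationary iff p < alpha.  Constant
    series are stationary by convention.
    """
    xv = _values(x)
    if xv.size < 20:
        raise ValueError("ADF needs n >= 20")
    if np.ptp(xv) == 0:
        logger.info("adf_stationary: constant series, stationary by convention")
        return True, 0.0
    try:
        p = float(adfuller(xv, autolag="AIC")[1])
    except Exception as exc:  # near-constant series can break the regression
        logger.warning("adfuller failed (%s); treating as stationary", exc)
        return True, 0.0
    return p < alpha, p


def _difference_to_stationary(xv: np.ndarray, yv: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray, int]:
    order = 0
    while order < MAX_DIFFERENCING:
        ok_x, _ = adf_stationary(xv, alpha)
        ok_y, _ = adf_stationary(yv, alpha)
        if ok_x and ok_y:
            return xv, yv, order
        xv, yv = np.diff(xv), np.diff(yv)
        order += 1
    ok_x, _ = adf_stationary(xv, alpha)
    ok_y, _ = adf_stationary(yv, alpha)
    if not (ok_x and ok_y):
        logger.warning("series still non-stationary after order-%d differencing", order)
    return xv, yv, order


def _lagged_pearson(xv: np.ndarray, yv: np.ndarray, shift: int) -> float:
    """Pearson r of x against y shifted by `shift` samples (y delayed)."""
    if shift >= 0:
        a, b = xv[: xv.size - shift or None], yv[shift:]
    else:
        a, b = xv[-shift:], yv[: yv.size + shift or None]
    if a.size < MIN_OVERLAP:
        return float("nan")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def cross_correlation(x, y, max_lag: float = 15.0, *, lag_step: float = 1.0,
                      alpha: float = 0.05, difference: bool = True) -> CrossCorrelation:
    """Cross-correlation over integer-second lags with ADF-driven differencing.

    Both series are differenced (order 1, at most twice) until the ADF test
    accepts stationarity for both; lags where the overlap falls under 30
    samples are recorded as missing.  ``x`` is the independent / reference
    series: a positive ``best_lag`` means ``y`` lags behind ``x``.
    """
    xv, yv = _values(x), _values(y)
    if xv.size != yv.size:
        raise ValueError("series must share a grid")
    res_ms = _resolution_ms(x)
    step = max(1, int(round(lag_step * 1000.0 / res_ms)))
    order = 0
    if difference:
        xv, yv, order = _difference_to_stationary(xv, yv, alpha)
    n_lags = int(round(max_lag / lag_step))
    lags = np.arange(-n_lags, n_lags + 1) * lag_step
    coefs = np.array([_lagged_pearson(xv, yv, int(k) * step)
                      for k in range(-n_lags, n_lags + 1)])
    if np.all(np.isnan(coefs)):
        best = float("nan")
    else:
        best = float(lags[int(np.nanargmax(coefs))])
    return CrossCorrelation(lags=lags, coefficients=coefs, best_lag=best,
                            differenced=order)


def mic(x, y, cfg: MICConfig = MICConfig()) -> float:
    """Maximal Information Coefficient of a channel pair (in [0, 1])."""
    xv, yv = _values(x), _values(y)
    if xv.size != yv.size:
        raise ValueError("series must have equal length")
    if xv.size < 25:
        raise ValueError("MIC needs n >= 25")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("mic: constant input, returning 0")
        return 0.0
    return mic_score(xv, yv, alpha=cfg.alpha, c=cfg.c, exact_n=cfg.exact_n)


def classify_association(mic_val: float, r2_val: float, epsilon: float = 0.1) -> AssociationClass:
    """Classify a pair by the nonlinearity score MIC - R^2.

    score < -epsilon: the MIC does not confirm the linear fit ("false"
    linear); |score| <= epsilon: "true" linear; score > epsilon: functional
    but not linear.
    """
    for label, val in (("mic", mic_val), ("r2", r2_val)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1], got {val}")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    score = mic_val - r2_val
    if score < -epsilon:
        value = "false_linear"
    elif score > epsilon:
        value = "nonlinear_functional"
    else:
        value = "true_linear"
    return AssociationClass(value=value, score=float(score), epsilon=float(epsilon))


def cluster_pairs(profile_matrix: pd.DataFrame, k: int = 3, seed: int = 0,
                  n_init: int = 25) -> pd.Series:
    """k-means clustering of per-pair MIC profiles across participants.

    Rows are pairs, columns participants; missing cells are imputed with the
    pair mean.  Clusters are relabelled by ascending centroid mean — for
    k = 3 the labels are low / moderate / high.
    """
    if len(profile_matrix) < k:
        raise ValueError(f"need at least k={k} pairs, got {len(profile_matrix)}")
    if k < 2:
        raise ValueError("k must be >= 2")
    X = profile_matrix.to_numpy(dtype=float)
    row_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
    row_means = np.where(np.isnan(row_means), np.nanmean(X), row_means)
    inds = np.where(np.isnan(X))
    X[inds] = row_means[inds[0]]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    order = np.argsort(km.cluster_centers_.mean(axis=1), kind="stable")
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    if k == 3:
        labels = [CLUSTER_LEVELS[rank_of[c]] for c in raw]
    else:
        labels = [f"level_{rank_of[c]}" for c in raw]
    return pd.Series(labels, index=profile_matrix.index, name="cluster")
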