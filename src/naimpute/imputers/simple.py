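"""Single-value and left-censored imputers (the SV family).

Constant fills (zero / global minimum / column median / row median) and the
MNAR-oriented low-value imputers that assume missingness is detection-limit
censoring: MinDet (deterministic low quantile), MinProb (random draws around
a low quantile), PI (Perseus-style down-shifted normal) and QRILC
(quantile-regression fit of a left-truncated normal, draws from the censored
tail).  All operate per sample on log2 intensities.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .base import register


@register("zero", family="SV", tier="fast")
def impute_zero(X, seed=None):
    filled = np.where(np.isnan(X), 0.0, X)
    return filled, {}


@register("minimum", family="SV", tier="fast")
def impute_minimum(X, seed=None):
    obs = X[~np.isnan(X)]
    if obs.size == 0:
        raise ValueError("matrix has no observed values")
    return np.where(np.isnan(X), obs.min(), X), {}


@register("colmedian", family="SV", tier="fast")
def impute_colmedian(X, seed=None):
    if np.isnan(X).all(axis=0).any():
        raise ValueError("a sample has no observed values; column median undefined")
    med = np.nanmedian(X, axis=0)
    return np.where(np.isnan(X), med[None, :], X), {}


@register("rowmedian", family="SV", tier="fast")
def impute_rowmedian(X, seed=None):
    if np.isnan(X).all(axis=1).any():
        raise ValueError("a feature has no observed values; row median undefined")
    med = np.nanmedian(X, axis=1)
    return np.where(np.isnan(X), med[:, None], X), {}


def _col_quantile(X, q):
    if np.isnan(X).all(axis=0).any():
        raise ValueError("a sample has no observed values")
    return np.nanquantile(X, q, axis=0)


@register("mindet", family="SV", tier="fast")
def impute_mindet(X, seed=None, q: float = 0.01):
    """Deterministic per-sample low quantile (q=0 gives the sample minimum)."""
    lows = _col_quantile(X, q)
    return np.where(np.isnan(X), lows[None, :], X), {}


@register("minprob", family="SV", tier="fast", stochastic=True)
def impute_minprob(X, seed=None, q: float = 0.01, tune: float = 1.0):
    """Random draws centered at the per-sample q-quantile.

    Spread = ``tune`` x median of per-feature sds (the reference MinProb
    behaviour: a Gaussian around the MinDet value, no hard truncation).
    """
    rng = np.random.default_rng(seed)
    centers = _col_quantile(X, q)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feat_sds = np.nanstd(X, axis=1, ddof=1)
    sigma = tune * float(np.nanmedian(feat_sds))
    filled = X.copy()
    for j in range(X.shape[1]):
        miss = np.isnan(X[:, j])
        if not miss.any():
            continue
        filled[miss, j] = rng.normal(centers[j], max(sigma, 0.0), size=int(miss.sum()))
    return filled, {}


@register("pi", family="SV", tier="fast", stochastic=True)
def impute_pi(X, seed=None, shift: float = 1.8, width: float = 0.3):
    """Perseus-style down-shifted normal: N(mean - shift*sd, (width*sd)^2) per sample."""
    rng = np.random.default_rng(seed)
    filled = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError("a sample has no observed values")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1)) if obs.size > 1 else 0.0
        filled[miss, j] = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
    return filled, {}


@register("qrilc", family="SV", tier="fast", stochastic=True)
def impute_qrilc(X, seed=None, fit_quantile: float = 0.25, mindet_q: float = 0.01):
    """Quantile-regression imputation of left-censored data.

    Per sample: the full (uncensored) normal is estimated by regressing the
    observed order statistics on standard-normal quantiles over the upper
    1 - ``fit_quantile`` of the empirical distribution (the left tail is the
    censored part and is excluded from the fit); imputed values are then
    drawn from the censored tail of the fitted normal, i.e. truncated above
    at the fitted quantile matching the sample's missing fraction.  Samples
    with < 5 observed values fall back to MinDet with a warning.
    """
    rng = np.random.default_rng(seed)
    filled = X.copy()
    fallback = False
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = np.sort(col[~miss])
        n = obs.size
        if n < 5:
            fallback = True
            filled[miss, j] = np.nanquantile(col, mindet_q)
            continue
        # The observed order statistics are quantiles of the *truncated*
        # distribution; map them to full-distribution probabilities by
        # reserving the censored mass (the missing fraction) on the left.
        miss_frac = float(np.clip(miss.sum() / (miss.sum() + n), 1e-3, 1 - 1e-3))
        p_obs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
        p_full = miss_frac + (1 - miss_frac) * p_obs
        upper = p_obs >= fit_quantile
        z = stats.norm.ppf(p_full[upper])
        slope, intercept = np.polyfit(z, obs[upper], 1)
        mu, sd = float(intercept), float(slope)
        if sd <= 0:
            filled[miss, j] = float(obs[0])
            continue
        # truncation point: the fitted quantile at the censored mass
        b = stats.norm.ppf(miss_frac)
        draws = stats.truncnorm.rvs(-np.inf, b, loc=mu, scale=sd,
                                    size=int(miss.sum()), random_state=rng)
        filled[miss, j] = draws
    if fallback:
        warnings.warn("qrilc: samples with < 5 observed values fell back to mindet")
    return filled, {}
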