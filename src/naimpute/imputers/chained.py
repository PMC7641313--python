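"""Chained-equations imputation engine.

One engine serves the regression-based slow tier and the ridge-regression
method: missing cells start at the feature mean; for ``n_iter`` rounds, each
incomplete feature is regressed (across samples) on all other features'
current values, training on its observed samples and re-predicting its
missing ones.  Engines:

* ``norm``   -- Bayesian linear regression with a posterior noise draw
* ``cart``   -- regression tree
* ``rf``     -- random forest
* ``robust`` -- Huber regression (iteratively reweighted; the IRM engine)
* ``ridge``  -- L2-penalized linear regression (the GRR method)

``n_iter=0`` returns the mean-imputed matrix (the initialization contract).
An engine failure on a feature falls back to the feature mean for that round
with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import BayesianRidge, HuberRegressor, Ridge
from sklearn.tree import DecisionTreeRegressor

from .._util import derive_seed
from .base import register

_ENGINES = ("norm", "cart", "rf", "robust", "ridge")


def _make_model(engine: str, seed: int | None, params: dict):
    if engine == "norm":
        return BayesianRidge(**params)
    if engine == "cart":
        return DecisionTreeRegressor(random_state=seed, **params)
    if engine == "rf":
        params.setdefault("n_estimators", 30)
        return RandomForestRegressor(random_state=seed, **params)
    if engine == "robust":
        return HuberRegressor(**params)
    if engine == "ridge":
        params.setdefault("alpha", 1e-3)
        return Ridge(**params)
    raise ValueError(f"unknown engine {engine!r}; choose from {_ENGINES}")


def impute_chained(X, seed=None, engine: str = "ridge", n_iter: int = 10, **engine_params):
    n, s = X.shape
    if n < 2:
        raise ValueError("chained imputation needs at least 2 features")
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        raise ValueError("feature with no observed values")
    filled = X.copy()
    row_means = np.nanmean(X, axis=1)
    filled[miss] = np.broadcast_to(row_means[:, None], X.shape)[miss]
    if not miss.any() or n_iter == 0:
        return filled, {"iterations": 0, "engine": engine}
    stochastic = engine in ("norm", "cart", "rf")
    rng = np.random.default_rng(seed) if engine == "norm" else None
    incomplete = np.flatnonzero(miss.any(axis=1))
    order = incomplete[np.argsort(miss[incomplete].sum(axis=1), kind="stable")]
    n_failures = 0
    for it in range(int(n_iter)):
        for i in order:
            obs = ~miss[i]
            others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            Z = filled[others].T  # samples x (n-1)
            model_seed = derive_seed(seed, engine, it, int(i)) if (stochastic and seed is not None) else None
            try:
                model = _make_model(engine, model_seed, dict(engine_params))
                model.fit(Z[obs], X[i, obs])
                if engine == "norm":
                    pred, pred_std = model.predict(Z[~obs], return_std=True)
                    pred = pred + rng.normal(0.0, pred_std)
                else:
                    pred = model.predict(Z[~obs])
            except Exception as exc:  # noqa: BLE001 - engine failure falls back to mean
                warnings.warn(f"chained/{engine} failed on feature {i}: {exc}; mean fill")
                pred = row_means[i]
                n_failures += 1
            filled[i, ~miss[i]] = X[i, ~miss[i]]
            filled[i, miss[i]] = pred
    return filled, {"iterations": int(n_iter), "engine": engine, "failures": n_failures}


@register("grr", family="LS", tier="fast")
def impute_grr(X, seed=None, n_iter: int = 10, alpha: float = 1e-3):
    """Generalized ridge regression via the chained engine (L2-penalized)."""
    return impute_chained(X, seed=seed, engine="ridge", n_iter=n_iter, alpha=alpha)


@register("irm", family="LS", tier="slow")
def impute_irm(X, seed=None, n_iter: int = 10, **params):
    """Iterative robust-regression imputation (Huber loss)."""
    return impute_chained(X, seed=seed, engine="robust", n_iter=n_iter, **params)


@register("mice_norm", family="LS", tier="slow", stochastic=True)
def impute_mice_norm(X, seed=None, n_iter: int = 10, **params):
    """Chained equations with Bayesian linear regression and noise draws."""
    return impute_chained(X, seed=seed, engine="norm", n_iter=n_iter, **params)


@register("mice_cart", family="LS", tier="slow", stochastic=True)
def impute_mice_cart(X, seed=None, n_iter: int = 10, **params):
    """Chained equations with regression trees."""
    return impute_chained(X, seed=seed, engine="cart", n_iter=n_iter, **params)


@register("rf", family="LS", tier="slow", stochastic=True)
def impute_rf(X, seed=None, n_iter: int = 5, **params):
    """Chained equations with random-forest regression."""
    return impute_chained(X, seed=seed, engine="rf", n_iter=n_iter, **params)
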