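"""Local-similarity imputers: KNN, sequential KNN, and local least squares.

These exploit the strong local correlation structure of peptide-level data
(charge states of one peptide and peptides of one protein co-vary across
samples), borrowing each missing value from the most similar feature
profiles.
"""

from __future__ import annotations

import warnings

import numpy as np

from .base import register

_EPS = 1e-12


def _pairwise_rms_distance(X: np.ndarray) -> np.ndarray:
    """Root-mean-square difference over jointly observed samples, all feature pairs.

    Using the *mean* over the joint support (rather than the raw sum) keeps
    distances comparable between pairs with different numbers of jointly
    observed samples.  Pairs with no joint support get distance inf.
    """
    W = ~np.isnan(X)
    A = np.where(W, X, 0.0)
    Wf = W.astype(float)
    n_joint = Wf @ Wf.T
    S = A @ A.T
    Q = (A * A) @ Wf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = (Q + Q.T - 2.0 * S) / n_joint
    dist = np.sqrt(np.clip(msd, 0.0, None))
    dist[n_joint == 0] = np.inf
    return dist


def _weighted_pick(values: np.ndarray, dists: np.ndarray) -> float:
    """1/distance-weighted average; zero-distance neighbors get uniform weights."""
    zero = dists <= _EPS
    if zero.any():
        return float(values[zero].mean())
    w = 1.0 / dists
    return float(np.sum(w * values) / np.sum(w))


@register("knn", family="LS", tier="fast")
def impute_knn(X, seed=None, k: int = 10):
    """Weighted k-nearest-neighbour imputation over feature profiles.

    For each incomplete feature the k nearest features (RMS distance over
    jointly observed samples, ties broken by input order) supply a
    1/distance-weighted average at every missing sample; neighbours missing
    at that sample are skipped, and if none of the k has a value there the
    feature's own observed mean is used.
    """
    n, s = X.shape
    if n < k + 1:
        raise ValueError(f"knn needs at least k+1={k + 1} features")
    if np.isnan(X).all(axis=1).any():
        raise ValueError("feature with no observed values")
    dist = _pairwise_rms_distance(X)
    np.fill_diagonal(dist, np.inf)
    filled = X.copy()
    row_means = np.nanmean(X, axis=1)
    fallbacks = 0
    for i in np.flatnonzero(np.isnan(X).any(axis=1)):
        order = np.argsort(dist[i], kind="stable")
        nbrs = order[np.isfinite(dist[i][order])][:k]
        for j in np.flatnonzero(np.isnan(X[i])):
            vals = X[nbrs, j]
            have = ~np.isnan(vals)
            if not have.any():
                filled[i, j] = row_means[i]
                fallbacks += 1
            else:
                filled[i, j] = _weighted_pick(vals[have], dist[i][nbrs][have])
    return filled, {"mean_fallbacks": fallbacks}


@register("seqknn", family="LS", tier="fast")
def impute_seqknn(X, seed=None, k: int = 10):
    """Sequential KNN: features imputed in ascending-NA order against a growing pool.

    The pool starts as the complete features; each imputed feature joins the
    pool, so heavily-missing features can borrow from previously imputed
    ones.  Ties in NA count are broken by input order.
    """
    n, s = X.shape
    na_count = np.isnan(X).sum(axis=1)
    pool_idx = list(np.flatnonzero(na_count == 0))
    if not pool_idx:
        raise ValueError("seqknn needs at least one complete feature")
    filled = X.copy()
    order = np.argsort(na_count, kind="stable")
    for i in order:
        if na_count[i] == 0:
            continue
        pool = np.asarray(pool_idx)
        obs = ~np.isnan(X[i])
        diffs = filled[pool][:, obs] - X[i, obs]
        d = np.sqrt(np.mean(diffs * diffs, axis=1))
        nearest = np.argsort(d, kind="stable")[: min(k, pool.size)]
        nbrs, nd = pool[nearest], d[nearest]
        for j in np.flatnonzero(~obs):
            filled[i, j] = _weighted_pick(filled[nbrs, j], nd)
        pool_idx.append(int(i))
    return filled, {}


@register("lls", family="LS", tier="fast")
def impute_lls(X, seed=None, k: int = 10, ridge: float = 1e-8):
    """Local least squares: regress each incomplete feature on its k most
    correlated complete features (by |Pearson| over the target's observed
    samples) and predict at the missing samples.

    If fewer than k complete features exist, k is clamped with a warning
    (only a matrix with zero complete features is an error).  A singular
    normal-equation system falls back to a tiny ridge penalty.
    """
    n, s = X.shape
    complete = np.flatnonzero(~np.isnan(X).any(axis=1))
    if complete.size == 0:
        raise ValueError("lls needs at least one complete feature")
    if complete.size < k:
        warnings.warn(f"lls: only {complete.size} complete features; k clamped from {k}")
        k = int(complete.size)
    C = X[complete]
    filled = X.copy()
    for i in np.flatnonzero(np.isnan(X).any(axis=1)):
        obs = ~np.isnan(X[i])
        y = X[i, obs]
        if y.size < 2 or np.std(y) == 0:
            filled[i, ~obs] = float(np.mean(y))
            continue
        Co = C[:, obs]
        yc = y - y.mean()
        Cc = Co - Co.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.sum(Cc * Cc, axis=1) * np.sum(yc * yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(np.sum(Cc * yc, axis=1) / denom)
        r = np.where(np.isfinite(r), r, 0.0)
        # never fit more coefficients than the observed samples can support
        k_eff = min(k, max(1, y.size - 2))
        sel = np.argsort(-r, kind="stable")[:k_eff]
        Z = np.column_stack([np.ones(y.size), Co[sel].T])  # n_obs x (k_eff+1)
        # pseudoinverse solve: small singular values of a collinear neighbour
        # set are truncated instead of amplified
        try:
            beta, *_ = np.linalg.lstsq(Z, y, rcond=1e-8)
        except np.linalg.LinAlgError:
            warnings.warn("lls: singular design; ridge fallback")
            G = Z.T @ Z
            beta = np.linalg.solve(G + ridge * np.eye(G.shape[0]), Z.T @ y)
        Zmiss = np.column_stack([np.ones(int((~obs).sum())), C[sel][:, ~obs].T])
        filled[i, ~obs] = Zmiss @ beta
    return filled, {"k": k}
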