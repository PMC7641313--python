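"""Global-structure imputers (GS family): iterative SVD, Gaussian EM (MLE)
and sequential conditional-mean imputation (Impseq / Impseqrob).

These assume a global covariance structure across samples: low-rank signal
for SVD, a multivariate normal over the sample dimension for MLE/Impseq
(features are treated as i.i.d. draws of a sample-dimensional Gaussian).
"""

from __future__ import annotations

import warnings

import numpy as np

from .base import register


@register("svd", family="GS", tier="fast")
def impute_svd(X, seed=None, rank: int = 5, tol: float = 1e-2, max_iter: int = 100):
    """Iterative truncated-SVD completion.

    Missing cells start at the feature mean; each iteration reconstructs the
    matrix at the given rank and rewrites only the missing cells, until the
    relative change of the imputed cells drops below ``tol``.
    """
    n, s = X.shape
    rank = int(rank)
    if rank < 1 or rank >= min(n, s):
        raise ValueError(f"rank must be in [1, {min(n, s) - 1}]")
    miss = np.isnan(X)
    if not miss.any():
        return X.copy(), {"iterations": 0, "converged": True}
    if miss.all(axis=1).any():
        raise ValueError("feature with no observed values")
    filled = X.copy()
    row_means = np.nanmean(X, axis=1)
    filled[miss] = np.broadcast_to(row_means[:, None], X.shape)[miss]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U, sv, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :rank] * sv[:rank]) @ Vt[:rank]
        old = filled[miss]
        new = recon[miss]
        delta = np.linalg.norm(new - old) / max(np.linalg.norm(old), 1e-12)
        filled[miss] = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"svd imputation did not converge in {max_iter} iterations")
    return filled, {"iterations": it, "converged": converged}


def _pattern_groups(miss: np.ndarray) -> dict[bytes, np.ndarray]:
    keys = np.packbits(miss, axis=1)
    out: dict[bytes, list[int]] = {}
    for i, key in enumerate(keys):
        out.setdefault(key.tobytes(), []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


@register("mle", family="GS", tier="fast")
def impute_mle_em(X, seed=None, ridge: float = 1e-6, tol: float = 1e-6, max_iter: int = 500):
    """Maximum-likelihood imputation via EM for a multivariate normal.

    Features are i.i.d. observations of an ``n_samples``-dimensional Gaussian.
    E-step: missing entries of each feature are replaced by their conditional
    expectation given the observed entries (with the conditional covariance
    entering the scatter update); M-step: mean/covariance re-estimated with a
    small ridge on the diagonal.  Missing cells are the conditional means at
    convergence.
    """
    n, s = X.shape
    miss = np.isnan(X)
    if not miss.any():
        return X.copy(), {"iterations": 0, "converged": True}
    if miss.all(axis=1).any():
        raise ValueError("feature with no observed values")
    mu = np.nanmean(X, axis=0)
    filled = X.copy()
    filled[miss] = np.broadcast_to(mu[None, :], X.shape)[miss]
    sigma = np.cov(filled, rowvar=False) + ridge * np.eye(s)
    patterns = _pattern_groups(miss)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = filled[miss].copy()
        cc_sum = np.zeros((s, s))
        for rows in patterns.values():
            pm = miss[rows[0]]
            if not pm.any():
                continue
            o, mi = ~pm, pm
            soo = sigma[np.ix_(o, o)]
            B = np.linalg.solve(soo, sigma[np.ix_(o, mi)]).T  # m x o
            resid = X[np.ix_(rows, o)] - mu[o]
            filled[np.ix_(rows, mi)] = mu[mi] + resid @ B.T
            C = sigma[np.ix_(mi, mi)] - B @ sigma[np.ix_(o, mi)]
            full_C = np.zeros((s, s))
            full_C[np.ix_(mi, mi)] = C
            cc_sum += len(rows) * full_C
        mu = filled.mean(axis=0)
        centred = filled - mu
        sigma = (centred.T @ centred + cc_sum) / n + ridge * np.eye(s)
        delta = np.max(np.abs(filled[miss] - prev))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"mle EM did not converge in {max_iter} iterations")
    return filled, {"iterations": it, "converged": converged, "mu": mu, "sigma": sigma}


def _conditional_fill(x: np.ndarray, mu: np.ndarray, S: np.ndarray, ridge: float) -> np.ndarray:
    """Fill NaNs of one profile with the Gaussian conditional mean."""
    mi = np.isnan(x)
    o = ~mi
    soo = S[np.ix_(o, o)]
    try:
        w = np.linalg.solve(soo, x[o] - mu[o])
    except np.linalg.LinAlgError:
        warnings.warn("impseq: singular scatter; ridge fallback")
        soo = soo + ridge * np.trace(soo) / max(soo.shape[0], 1) * np.eye(soo.shape[0])
        w = np.linalg.solve(soo, x[o] - mu[o])
    out = x.copy()
    out[mi] = mu[mi] + S[np.ix_(mi, o)] @ w
    return out


def _impseq(X, robust: bool, ridge: float = 1e-8):
    n, s = X.shape
    miss = np.isnan(X)
    if not miss.any():
        return X.copy(), {"robust": robust}
    if miss.all(axis=1).any():
        raise ValueError("feature with no observed values")
    complete = np.flatnonzero(~miss.any(axis=1))

    def winsorize(block: np.ndarray) -> np.ndarray:
        med = np.median(block, axis=0)
        mad = 1.4826 * np.median(np.abs(block - med), axis=0)
        mad = np.where(mad > 0, mad, np.std(block, axis=0) + 1e-12)
        return np.clip(block, med - 3 * mad, med + 3 * mad)

    if complete.size >= s + 1:
        seedblock = X[complete]
    else:
        # Too few fully observed features to seed a covariance: fall back to a
        # mean-filled estimate so the sequential pass can still run.
        warnings.warn(
            f"impseq: only {complete.size} complete features (< n_samples+1); "
            "seeding scatter from the mean-filled matrix"
        )
        seedblock = X.copy()
        row_means = np.nanmean(X, axis=1)
        seedblock[miss] = np.broadcast_to(row_means[:, None], X.shape)[miss]
    if robust:
        mu = np.median(seedblock, axis=0)
        S = np.cov(winsorize(seedblock), rowvar=False)
    else:
        mu = seedblock.mean(axis=0)
        S = np.cov(seedblock, rowvar=False)
    S = S + ridge * np.eye(s)

    # running Welford-style accumulators seeded from the seed block
    n_acc = seedblock.shape[0]
    mean_acc = mu.copy()
    M2 = S * max(n_acc - 1, 1)

    filled = X.copy()
    na_count = miss.sum(axis=1)
    order = np.argsort(na_count, kind="stable")
    for i in order:
        if na_count[i] == 0:
            continue
        x = _conditional_fill(X[i], mean_acc, M2 / max(n_acc - 1, 1), ridge)
        filled[i] = x
        if robust:
            scale = np.sqrt(np.diag(M2) / max(n_acc - 1, 1))
            upd = np.clip(x, mean_acc - 3 * scale, mean_acc + 3 * scale)
        else:
            upd = x
        n_acc += 1
        delta = upd - mean_acc
        mean_acc = mean_acc + delta / n_acc
        M2 = M2 + np.outer(delta, upd - mean_acc)
    return filled, {"robust": robust, "n_seed": int(seedblock.shape[0])}


@register("impseq", family="GS", tier="fast")
def impute_impseq(X, seed=None):
    """Sequential conditional-mean imputation under a running Gaussian model.

    Location/scatter are seeded from the complete features; incomplete
    features are processed in ascending-NA order, filled with the conditional
    mean given their observed entries, and folded into the running moments.
    """
    return _impseq(X, robust=False)


@register("impseqrob", family="GS", tier="fast")
def impute_impseqrob(X, seed=None):
    """Robust variant of impseq: median/MAD-winsorized moment updates."""
    return _impseq(X, robust=True)
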