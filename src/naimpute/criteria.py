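"""Classic imputation-evaluation criteria.

Four scores over the masked-cell experiment:

* NRMSE  = sqrt( mean((y_o - y_i)^2) / var(y_o) ), lower is better
  (sample variance, n-1 denominator).
* SOR    = sum over missing variables of the method's per-variable NRMSE
  rank among all compared methods, lower is better.  Variables with a
  single masked cell rank by squared error (variance is undefined there).
* ACC_OI = Pearson r between original and imputed values, higher is better.
  Constant imputations (zero, minimum, ...) have sd(y_i)=0 and score
  "no result" rather than a number.
* PSS    = Procrustes statistic: residual sum of squares after optimally
  translating / rotating / scaling the imputed matrix's PCA sample
  configuration onto the original's, lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes

from .data import ExpressionMatrix
from .masking import MaskedEvaluation

__all__ = ["CriterionScore", "nrmse", "sor", "acc_oi", "pss_procrustes"]


@dataclass
class CriterionScore:
    criterion_name: str
    value: float | None
    direction: str  # lower_better / higher_better
    n_used: int
    reason: str | None = None  # why the value is missing, when it is

    @property
    def is_missing(self) -> bool:
        return self.value is None


def nrmse(ev: MaskedEvaluation) -> CriterionScore:
    """Root mean squared error normalized by the variance of the true values."""
    y_o, y_i = ev.y_o, ev.y_i
    if len(y_o) < 2:
        return CriterionScore("NRMSE", None, "lower_better", len(y_o), "fewer than 2 masked cells")
    var = float(np.var(y_o, ddof=1))
    if var <= 0:
        return CriterionScore("NRMSE", None, "lower_better", len(y_o), "zero variance of original values")
    value = float(np.sqrt(np.mean((y_o - y_i) ** 2) / var))
    return CriterionScore("NRMSE", value, "lower_better", len(y_o))


def _per_variable_stat(y_o: np.ndarray, y_i: np.ndarray) -> float:
    """Per-variable NRMSE; squared error when it degenerates (1 cell / 0 variance)."""
    if len(y_o) >= 2:
        var = float(np.var(y_o, ddof=1))
        if var > 0:
            return float(np.sqrt(np.mean((y_o - y_i) ** 2) / var))
    return float(np.mean((y_o - y_i) ** 2))


def sor(evs_by_method: dict[str, MaskedEvaluation]) -> dict[str, CriterionScore]:
    """NRMSE-based sum of ranks across missing variables.

    For every feature holding >= 1 masked cell, methods are ranked ascending
    by their per-variable statistic (average ranks on ties); SOR is the sum
    of a method's ranks over all such variables.
    """
    methods = list(evs_by_method)
    if len(methods) < 2:
        raise ValueError("sor needs at least 2 methods")
    ref = evs_by_method[methods[0]]
    for name, ev in evs_by_method.items():
        if len(ev.y_o) != len(ref.y_o) or not np.array_equal(ev.feature_index, ref.feature_index):
            raise ValueError(f"method {name!r} was evaluated on different masked coordinates")
    totals = {name: 0.0 for name in methods}
    variables = np.unique(ref.feature_index)
    for var_idx in variables:
        sel = ref.feature_index == var_idx
        stats_here = np.array(
            [_per_variable_stat(evs_by_method[name].y_o[sel], evs_by_method[name].y_i[sel]) for name in methods]
        )
        ranks = stats.rankdata(stats_here, method="average")
        for name, r in zip(methods, ranks):
            totals[name] += float(r)
    n_vars = len(variables)
    return {
        name: CriterionScore("SOR", totals[name], "lower_better", n_vars) for name in methods
    }


def acc_oi(ev: MaskedEvaluation) -> CriterionScore:
    """Pearson correlation between original and imputed values."""
    y_o, y_i = ev.y_o, ev.y_i
    n = len(y_o)
    if n < 3:
        return CriterionScore("ACC_OI", None, "higher_better", n, "fewer than 3 masked cells")
    if np.std(y_i) == 0 or np.std(y_o) == 0:
        return CriterionScore(
            "ACC_OI", None, "higher_better", n,
            "no result: standard deviation of imputed values is 0",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-constant inputs already handled above
        r = float(stats.pearsonr(y_o, y_i).statistic)
    return CriterionScore("ACC_OI", r, "higher_better", n)


def _pca_scores(m: ExpressionMatrix, n_components: int) -> np.ndarray:
    """Sample-score configuration (samples x n_components) from PCA.

    Samples are the observations, features the variables; scores are the
    projections onto the leading principal axes (column-centered data).
    """
    X = m.values.T  # samples x features
    Xc = X - X.mean(axis=0)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, :n_components] * sv[:n_components]


def pss_procrustes(
    original: ExpressionMatrix, imputed: ExpressionMatrix, n_components: int = 2
) -> CriterionScore:
    """Procrustes statistic between the PCA sample configurations.

    The imputed configuration is optimally translated, rotated/reflected and
    isotropically scaled onto the original's; the score is the residual sum
    of squared differences (0 when the configurations agree up to a
    similarity transform, e.g. PCA axis sign flips).
    """
    if original.values.shape != imputed.values.shape:
        raise ValueError("matrices must share dimensions")
    max_nc = min(original.n_samples, original.n_features)
    if n_components > max_nc:
        warnings.warn(f"n_components clamped from {n_components} to {max_nc}")
        n_components = max_nc
    Xs = _pca_scores(original, n_components)
    Ys = _pca_scores(imputed, n_components)
    Xc = Xs - Xs.mean(axis=0)
    Yc = Ys - Ys.mean(axis=0)
    ynorm2 = float(np.sum(Yc * Yc))
    if ynorm2 <= 0:
        value = float(np.sum(Xc * Xc))
    else:
        R, sv_sum = orthogonal_procrustes(Yc, Xc)
        scale = float(sv_sum) / ynorm2
        value = float(np.sum((Xc - scale * (Yc @ R)) ** 2))
    return CriterionScore("PSS", value, "lower_better", original.n_samples)
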