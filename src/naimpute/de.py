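"""Differential-expression analysis and the replicate-subsampling simulation.

After imputation the complete matrix supports a standard two-group analysis:
per-feature two-tailed Student's t-test (equal variance; Welch by flag) on
log2 intensities, Benjamini-Hochberg correction, and the conjunction rule
BH-adjusted p < alpha AND |log2FC| > fc_threshold (default 0.585, i.e. a
1.5-fold change).  log2FC = mean(first design group) - mean(second).

The subsampling simulation mimics routine small-cohort designs: draw k
replicates per group without replacement, repeat, and report the per-repeat
significant counts plus per-feature medians (p, BH p, log2FC) for
median-of-repeats volcano construction.  Comparing the subsampled calls to
the full-data "gold standard" measures how much statistical power a smaller
design or a poorer imputation sacrifices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import derive_seed
from .data import ExpressionMatrix, SampleDesign

__all__ = ["differential_expression", "subsample_de", "gold_standard_compare"]

DEFAULT_FC_THRESHOLD = 0.585  # log2(1.5) to the paper's printed precision


def _group_columns(m: ExpressionMatrix, design: SampleDesign) -> tuple[list[int], list[int], tuple[str, str]]:
    design.validate_against(m)
    labels = design.group_labels
    if len(labels) != 2:
        raise ValueError(f"differential expression needs exactly 2 groups, got {labels}")
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    a = [pos[s] for s in design.samples_of(labels[0])]
    b = [pos[s] for s in design.samples_of(labels[1])]
    return a, b, (labels[0], labels[1])


def differential_expression(
    m: ExpressionMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-group t-test with BH correction on a complete log2 matrix."""
    if m.n_missing:
        raise ValueError("differential expression requires a complete (imputed) matrix")
    a_idx, b_idx, (label_a, label_b) = _group_columns(m, design)
    X = m.values
    A, B = X[:, a_idx], X[:, b_idx]
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate-variance rows handled below
        tstat, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    # zero variance in both groups: p=1 when means agree, 0 when they differ
    degenerate = np.isnan(p)
    p = np.where(degenerate, np.where(np.isclose(log2fc, 0.0), 1.0, 0.0), p)
    bh = multipletests(p, method="fdr_bh")[1]
    significant = (bh < alpha) & (np.abs(log2fc) > fc_threshold)
    direction = np.where(~significant, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "log2fc": log2fc,  # mean(first group) - mean(second group)
            "p_value": p,
            "bh_adjusted_p": bh,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    ).reset_index(drop=True)


def subsample_de(
    m: ExpressionMatrix,
    design: SampleDesign,
    k_per_group: int,
    n_repeats: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    equal_var: bool = True,
) -> dict:
    """Random-k replicate subsampling repeated ``n_repeats`` times.

    Returns per-repeat significant counts and per-feature medians of p,
    BH-adjusted p and log2FC across repeats ("Random 5" / "Random 3" style).
    """
    a_idx, b_idx, labels = _group_columns(m, design)
    if k_per_group > min(len(a_idx), len(b_idx)):
        raise ValueError(
            f"k_per_group={k_per_group} exceeds a group size ({len(a_idx)} vs {len(b_idx)})"
        )
    if k_per_group < 2:
        raise ValueError("k_per_group must be >= 2")
    rng = np.random.default_rng(derive_seed(seed, "subsample_de", k_per_group))
    sample_ids = m.sample_ids
    counts = np.zeros(n_repeats, dtype=int)
    p_all = np.empty((n_repeats, m.n_features))
    bh_all = np.empty((n_repeats, m.n_features))
    fc_all = np.empty((n_repeats, m.n_features))
    for r in range(n_repeats):
        sub_a = rng.choice(a_idx, size=k_per_group, replace=False)
        sub_b = rng.choice(b_idx, size=k_per_group, replace=False)
        cols = list(sub_a) + list(sub_b)
        sub_design = SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": [sample_ids[c] for c in cols],
                    "group_label": [labels[0]] * k_per_group + [labels[1]] * k_per_group,
                }
            )
        )
        sub_matrix = ExpressionMatrix(m.data.iloc[:, cols], m.scale)
        res = differential_expression(sub_matrix, sub_design, alpha, fc_threshold, equal_var)
        counts[r] = int(res["significant"].sum())
        p_all[r] = res["p_value"].to_numpy()
        bh_all[r] = res["bh_adjusted_p"].to_numpy()
        fc_all[r] = res["log2fc"].to_numpy()
    per_feature = pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "median_p": np.median(p_all, axis=0),
            "median_bh_p": np.median(bh_all, axis=0),
            "median_log2fc": np.median(fc_all, axis=0),
        }
    )
    per_feature["significant"] = (per_feature["median_bh_p"] < alpha) & (
        per_feature["median_log2fc"].abs() > fc_threshold
    )
    return {
        "k_per_group": k_per_group,
        "n_repeats": n_repeats,
        "significant_counts": counts,
        "per_feature": per_feature,
    }


def gold_standard_compare(full: pd.DataFrame, sub: dict) -> dict:
    """Overlap between the full-data significant set and the median-based
    subsample calls (Jaccard index over feature ids)."""
    gold = set(full.loc[full["significant"], "feature_id"])
    pf = sub["per_feature"]
    called = set(pf.loc[pf["significant"], "feature_id"])
    union = gold | called
    jaccard = len(gold & called) / len(union) if union else 1.0
    return {
        "n_gold": len(gold),
        "n_sub_median": len(called),
        "n_overlap": len(gold & called),
        "jaccard": jaccard,
    }
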