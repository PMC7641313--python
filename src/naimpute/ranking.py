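"""Score normalization, method ranking, and the final / targeted checks.

Raw criterion scores are normalized so that 1 is always the best method:
higher-is-better criteria divide by the column maximum; lower-is-better
criteria (NRMSE, SOR, PSS) use min/value, keeping the ordering while making
the normalized scale uniform.  Ranks are 1 = best with average ties; methods
missing a criterion (e.g. zero-imputation's undefined ACC_OI) share that
criterion's worst rank positions.  Composite ranks are the weighted mean of
per-criterion ranks within a criteria family (classic or proteomic),
re-ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix
from .imputers import ImputationResult

__all__ = [
    "ScoreTable",
    "normalize_scores",
    "rank_methods",
    "final_check",
    "targeted_check",
    "CLASSIC_CRITERIA",
    "PROTEOMIC_CRITERIA",
]

CLASSIC_CRITERIA = ("NRMSE", "SOR", "ACC_OI", "PSS")
PROTEOMIC_CRITERIA = ("ACC_Charge", "ACC_PepProt", "ACC_Complex", "ACC_PPI")

DIRECTIONS = {
    "NRMSE": "lower_better",
    "SOR": "lower_better",
    "PSS": "lower_better",
    "ACC_OI": "higher_better",
    "ACC_Charge": "higher_better",
    "ACC_PepProt": "higher_better",
    "ACC_Complex": "higher_better",
    "ACC_PPI": "higher_better",
}


def normalize_scores(raw: pd.DataFrame, directions: dict[str, str]) -> pd.DataFrame:
    """Scale each criterion column so the best method scores 1 (NaN stays NaN)."""
    out = raw.copy().astype(float)
    for crit in raw.columns:
        col = out[crit]
        if col.notna().sum() == 0:
            continue
        if directions[crit] == "higher_better":
            mx = col.max()
            if mx == 0:
                continue  # normalization skipped; ranks still computable
            out[crit] = col / mx
        else:
            mn = col.min()
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(col.to_numpy() == 0, 1.0, mn / col.to_numpy())
            out[crit] = vals
    return out


def _criterion_ranks(col: pd.Series, direction: str) -> pd.Series:
    """Ranks within one criterion: 1 = best, average ties, missing share the worst positions."""
    vals = col.to_numpy(dtype=float)
    defined = ~np.isnan(vals)
    M, d = len(vals), int(defined.sum())
    ranks = np.full(M, np.nan)
    if d:
        keyed = vals[defined] if direction == "lower_better" else -vals[defined]
        ranks[defined] = stats.rankdata(keyed, method="average")
    if d < M:
        ranks[~defined] = (d + 1 + M) / 2.0  # average of the trailing positions
    return pd.Series(ranks, index=col.index)


def rank_methods(
    raw: pd.DataFrame,
    directions: dict[str, str],
    weights: dict[str, float] | None = None,
    family: str = "all",
) -> pd.DataFrame:
    """Per-criterion ranks plus the composite (weighted mean of ranks, re-ranked).

    ``family`` selects the criteria columns: "classic", "proteomic" or "all".
    A zero weight drops the criterion from the composite entirely.
    """
    if family == "classic":
        crits = [c for c in raw.columns if c in CLASSIC_CRITERIA]
    elif family == "proteomic":
        crits = [c for c in raw.columns if c in PROTEOMIC_CRITERIA]
    elif family == "all":
        crits = list(raw.columns)
    else:
        raise ValueError(f"unknown family {family!r}")
    if not crits:
        raise ValueError(f"no criteria available for family {family!r}")
    weights = dict(weights or {})
    ranks = pd.DataFrame({c: _criterion_ranks(raw[c], directions[c]) for c in crits})
    used = [c for c in crits if weights.get(c, 1.0) > 0]
    w = np.array([weights.get(c, 1.0) for c in used], dtype=float)
    composite = (ranks[used].to_numpy() * w).sum(axis=1) / w.sum()
    ranks["composite_score"] = composite
    ranks["composite_rank"] = stats.rankdata(composite, method="average")
    return ranks


@dataclass
class ScoreTable:
    """The benchmark deliverable: methods x criteria raw scores, normalized
    scores, missing-score reasons, and the two composite rank tables."""

    raw: pd.DataFrame
    normalized: pd.DataFrame
    ranks_classic: pd.DataFrame
    ranks_proteomic: pd.DataFrame | None
    reasons: pd.DataFrame
    directions: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_scores(cls, raw: pd.DataFrame, reasons: pd.DataFrame | None = None,
                    directions: dict[str, str] | None = None,
                    weights: dict[str, float] | None = None) -> "ScoreTable":
        directions = {**DIRECTIONS, **(directions or {})}
        normalized = normalize_scores(raw, directions)
        has_proteomic = any(c in raw.columns and raw[c].notna().any() for c in PROTEOMIC_CRITERIA)
        return cls(
            raw=raw,
            normalized=normalized,
            ranks_classic=rank_methods(raw, directions, weights, "classic"),
            ranks_proteomic=rank_methods(raw, directions, weights, "proteomic") if has_proteomic else None,
            reasons=reasons if reasons is not None else pd.DataFrame(index=raw.index),
            directions=directions,
        )


def final_check(normalized: pd.DataFrame, spread_threshold: float = 0.05) -> dict[str, bool]:
    """Flag criteria whose normalized scores barely differ across methods.

    Indiscriminate criteria (range < threshold) cannot guide method
    selection and deserve a second look.
    """
    if len(normalized.index) < 2:
        raise ValueError("final check needs at least 2 methods")
    flags = {}
    for crit in normalized.columns:
        col = normalized[crit].dropna()
        flags[crit] = bool(len(col) == 0 or (col.max() - col.min()) < spread_threshold)
    return flags


def targeted_check(
    original: ExpressionMatrix,
    results: list[ImputationResult],
    feature_ids: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Before/after table for specific features (spiked standards, housekeeping
    proteins, ...): observed range, imputed values, and an out-of-range flag
    when any imputed value falls outside the feature's observed min/max.

    Unknown feature ids are returned separately, not fatal.
    """
    known = set(original.feature_ids)
    unknown = [f for f in feature_ids if f not in known]
    rows = []
    for fid in feature_ids:
        if fid not in known:
            continue
        orig_row = original.data.loc[fid]
        miss = orig_row.isna()
        obs = orig_row[~miss]
        for res in results:
            imp_row = res.matrix.data.loc[fid]
            imputed_vals = imp_row[miss]
            if miss.sum() == 0:
                note, flag = "no imputed cells", False
            else:
                note = ""
                flag = bool((imputed_vals < obs.min()).any() or (imputed_vals > obs.max()).any())
            rows.append({
                "feature_id": fid,
                "method": res.method_name,
                "n_observed": int((~miss).sum()),
                "n_imputed": int(miss.sum()),
                "observed_min": float(obs.min()) if len(obs) else np.nan,
                "observed_max": float(obs.max()) if len(obs) else np.nan,
                "imputed_values": ";".join(f"{v:.4g}" for v in imputed_vals),
                "out_of_observed_range": flag,
                "note": note,
            })
    return pd.DataFrame(rows), unknown
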