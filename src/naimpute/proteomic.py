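"""Proteomics-specific evaluation criteria.

Bottom-up quantification carries built-in redundancy: charge states of one
peptide, peptides of one protein, and proteins of one complex or interaction
cluster should all co-vary across samples.  These criteria score an imputed
matrix by the average within-group pairwise Pearson correlation at four
biological levels:

* ACC_Charge  -- between charge states of each peptide
* ACC_PepProt -- between peptides of each protein
* ACC_Complex -- between proteins of each complex (CORUM-style catalog)
* ACC_PPI     -- between proteins of each PPI cluster (hu.MAP-style catalog)

Only groups with >= 2 members matched in the data contribute; the criterion
is the mean of per-group scores, each the mean correlation over all
unordered member pairs (``divisor="m"`` divides the pair sum by the member
count instead).  A good imputation preserves these coherence scores close to
the values computed on the original, fully observed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CriterionScore
from .data import ExpressionMatrix, FeatureAnnotation, GroupCatalog

__all__ = [
    "GroupedProfileSet",
    "build_groups",
    "group_pairwise_acc",
    "acc_charge",
    "acc_pepprot",
    "acc_complex",
    "acc_ppi",
    "per_group_scores",
]

LEVELS = ("charge", "peptide", "complex", "ppi_cluster")


@dataclass
class GroupedProfileSet:
    """Per-group member profile matrices (members x samples)."""

    groups: list  # of (group_id, np.ndarray members x samples)
    level: str


def _aggregate(profiles: np.ndarray, how: str) -> np.ndarray:
    """Summarize member rows into one profile (Top3 by abundance, or mean)."""
    if how == "top3" and profiles.shape[0] > 3:
        order = np.argsort(-np.nanmean(profiles, axis=1), kind="stable")[:3]
        profiles = profiles[order]
    return np.nanmean(profiles, axis=0)


def protein_profiles(
    m: ExpressionMatrix, ann: FeatureAnnotation | None, aggregate: str = "top3"
) -> pd.DataFrame:
    """Protein-level profiles (proteins x samples).

    Without annotation, features are taken to be proteins already; with
    annotation, each protein's profile is the mean of its top-3 most abundant
    member log2 profiles (``aggregate="mean"`` averages all members).
    """
    if ann is None:
        return m.data.copy()
    table = ann.for_matrix(m)
    table = table[table["protein_id"] != ""]
    X = m.data
    rows, index = [], []
    for pid, sub in table.groupby("protein_id", sort=False):
        profiles = X.loc[sub["feature_id"]].to_numpy()
        rows.append(_aggregate(profiles, aggregate))
        index.append(pid)
    return pd.DataFrame(rows, index=index, columns=m.sample_ids)


def build_groups(
    m: ExpressionMatrix,
    ann: FeatureAnnotation | None,
    catalog: GroupCatalog | None,
    level: str,
    aggregate: str = "top3",
) -> GroupedProfileSet:
    """Assemble the member-profile groups for one biological level.

    Groups with fewer than 2 matched members are dropped (a single member
    offers no pairwise correlation).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; choose from {LEVELS}")
    groups: list = []
    if level == "charge":
        if ann is None:
            raise ValueError("charge level needs a feature annotation")
        table = ann.for_matrix(m)
        table = table[table["peptide_sequence"] != ""]
        for seq, sub in table.groupby("peptide_sequence", sort=False):
            if len(sub) < 2:
                continue
            groups.append((seq, m.data.loc[sub["feature_id"]].to_numpy()))
    elif level == "peptide":
        if ann is None:
            raise ValueError("peptide level needs a feature annotation")
        table = ann.for_matrix(m)
        table = table[(table["peptide_sequence"] != "") & (table["protein_id"] != "")]
        for pid, sub in table.groupby("protein_id", sort=False):
            # one profile per peptide sequence (charge rows averaged)
            peps = []
            for _, pep_rows in sub.groupby("peptide_sequence", sort=False):
                peps.append(np.nanmean(m.data.loc[pep_rows["feature_id"]].to_numpy(), axis=0))
            if len(peps) < 2:
                continue
            groups.append((pid, np.vstack(peps)))
    else:  # complex / ppi_cluster
        if catalog is None:
            raise ValueError(f"{level} level needs a group catalog")
        prot = protein_profiles(m, ann, aggregate)
        avail = set(prot.index)
        for gid, members in catalog.groups.items():
            matched = sorted(members & avail)
            if len(matched) < 2:
                continue
            groups.append((gid, prot.loc[matched].to_numpy()))
    return GroupedProfileSet(groups, level)


def _group_score(profiles: np.ndarray, method: str, divisor: str) -> float | None:
    """Mean pairwise correlation within one group; None when no valid pair."""
    df = pd.DataFrame(profiles.T)  # samples x members
    corr = df.corr(method=method, min_periods=3).to_numpy()  # pairwise-complete
    m_members = profiles.shape[0]
    iu = np.triu_indices(m_members, k=1)
    vals = corr[iu]
    vals = vals[~np.isnan(vals)]  # zero-variance / insufficient pairs skipped
    if vals.size == 0:
        return None
    if divisor == "m":
        return float(vals.sum() / m_members)
    return float(vals.mean())


def per_group_scores(
    gps: GroupedProfileSet, method: str = "pearson", divisor: str = "pairs"
) -> pd.DataFrame:
    """Tidy per-group score table (group_id, level, m, group_score)."""
    rows = []
    for gid, profiles in gps.groups:
        rows.append((gid, gps.level, profiles.shape[0], _group_score(profiles, method, divisor)))
    return pd.DataFrame(rows, columns=["group_id", "level", "m", "group_score"])


_CRITERION_NAMES = {
    "charge": "ACC_Charge",
    "peptide": "ACC_PepProt",
    "complex": "ACC_Complex",
    "ppi_cluster": "ACC_PPI",
}


def group_pairwise_acc(
    gps: GroupedProfileSet, method: str = "pearson", divisor: str = "pairs"
) -> CriterionScore:
    """Average within-group pairwise correlation over all retained groups."""
    name = _CRITERION_NAMES[gps.level]
    scores = [s for _, profiles in gps.groups if (s := _group_score(profiles, method, divisor)) is not None]
    if not scores:
        return CriterionScore(name, None, "higher_better", 0, "no group with a valid member pair")
    return CriterionScore(name, float(np.mean(scores)), "higher_better", len(scores))


def _acc_at(m, ann, catalog, level, **kw) -> CriterionScore:
    try:
        gps = build_groups(m, ann, catalog, level, aggregate=kw.pop("aggregate", "top3"))
    except ValueError as exc:
        return CriterionScore(_CRITERION_NAMES[level], None, "higher_better", 0, str(exc))
    return group_pairwise_acc(gps, **kw)


def acc_charge(m: ExpressionMatrix, ann: FeatureAnnotation | None, **kw) -> CriterionScore:
    """Coherence between charge states of each peptide."""
    return _acc_at(m, ann, None, "charge", **kw)


def acc_pepprot(m: ExpressionMatrix, ann: FeatureAnnotation | None, **kw) -> CriterionScore:
    """Coherence between peptides of each protein."""
    return _acc_at(m, ann, None, "peptide", **kw)


def acc_complex(
    m: ExpressionMatrix, ann: FeatureAnnotation | None, catalog: GroupCatalog | None, **kw
) -> CriterionScore:
    """Coherence between proteins of each complex."""
    return _acc_at(m, ann, catalog, "complex", **kw)


def acc_ppi(
    m: ExpressionMatrix, ann: FeatureAnnotation | None, catalog: GroupCatalog | None, **kw
) -> CriterionScore:
    """Coherence between proteins of each interaction cluster."""
    return _acc_at(m, ann, catalog, "ppi_cluster", **kw)
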