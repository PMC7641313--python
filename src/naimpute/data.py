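"""Data model, file I/O and pre-imputation filtering.

The central object is :class:`ExpressionMatrix`: a feature x sample grid of
intensities with explicit missing cells (NaN).  Rows are peptide precursors,
phosphopeptides or proteins; columns are samples.  Raw-scale input is
log2-transformed on ingest (zeros and negative cells count as non-detections
and become missing), so everything downstream operates on log2 intensities.

Companion tables:

* :class:`FeatureAnnotation` -- feature id -> (peptide sequence, charge,
  protein id); powers the charge-state and peptide-per-protein criteria.
* :class:`GroupCatalog` -- named groups of protein ids (protein complexes or
  PPI clusters); powers the complex / PPI coherence criteria.
* :class:`SampleDesign` -- sample -> condition group, for differential
  expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_NA_TOKENS = ("NA", "NaN", "")

__all__ = [
    "ExpressionMatrix",
    "FeatureAnnotation",
    "GroupCatalog",
    "SampleDesign",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_groups",
    "read_design",
    "write_table",
    "completeness_summary",
    "filter_by_na",
    "filter_by_cv",
]


@dataclass
class ExpressionMatrix:
    """Feature x sample intensity grid; NaN marks a missing cell.

    ``scale`` is ``"log2"`` (the working scale for all computation) or
    ``"raw"`` (positive intensities, only seen transiently before the ingest
    transform).
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.data = self.data.astype(float)
        if self.scale == "raw":
            vals = self.data.to_numpy()
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError("raw-scale matrix contains non-positive observed values")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Float ndarray view (features x samples); NaN = missing."""
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids/scale, new grid."""
        if values.shape != self.data.shape:
            raise ValueError("shape mismatch")
        return ExpressionMatrix(
            pd.DataFrame(np.asarray(values, dtype=float), index=self.data.index, columns=self.data.columns),
            self.scale,
        )

    def subset_features(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.iloc[np.asarray(keep)], self.scale)


@dataclass
class FeatureAnnotation:
    """feature_id -> peptide_sequence / charge / protein_id mapping.

    Two rows may share a peptide sequence with different charges (distinct
    precursors of one peptide); feature ids are unique.
    """

    table: pd.DataFrame  # columns: feature_id, peptide_sequence, charge, protein_id

    def __post_init__(self) -> None:
        required = ["feature_id", "peptide_sequence", "charge", "protein_id"]
        for col in required:
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if self.table["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids in annotation")
        self.table = self.table[required].reset_index(drop=True)

    def for_matrix(self, m: ExpressionMatrix) -> pd.DataFrame:
        """Annotation rows for features present in the matrix, matrix order."""
        idx = self.table.set_index("feature_id")
        present = [f for f in m.feature_ids if f in idx.index]
        return idx.loc[present].reset_index()


@dataclass
class GroupCatalog:
    """Named protein groups (CORUM-like complexes or hu.MAP-like clusters)."""

    groups: dict[str, frozenset]
    kind: str = "complex"  # or "ppi_cluster"

    def __post_init__(self) -> None:
        if self.kind not in ("complex", "ppi_cluster"):
            raise ValueError(f"unknown catalog kind {self.kind!r}")
        self.groups = {str(g): frozenset(str(p) for p in members) for g, members in self.groups.items()}


@dataclass
class SampleDesign:
    """sample_id -> condition group label (two labels for DE)."""

    table: pd.DataFrame  # columns: sample_id, group_label

    def __post_init__(self) -> None:
        for col in ("sample_id", "group_label"):
            if col not in self.table.columns:
                raise ValueError(f"design missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        self.table = self.table[["sample_id", "group_label"]].astype(str).reset_index(drop=True)

    @property
    def group_labels(self) -> list[str]:
        """Distinct labels in first-appearance order (fixes the log2FC sign)."""
        return list(dict.fromkeys(self.table["group_label"]))

    def samples_of(self, label: str) -> list[str]:
        return self.table.loc[self.table["group_label"] == str(label), "sample_id"].tolist()

    def validate_against(self, m: ExpressionMatrix, min_per_group: int = 2) -> None:
        missing = set(self.table["sample_id"]) - set(m.sample_ids)
        if missing:
            raise ValueError(f"design samples not in matrix: {sorted(missing)}")
        for label in self.group_labels:
            if len(self.samples_of(label)) < min_per_group:
                raise ValueError(f"group {label!r} has < {min_per_group} samples")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(
    path,
    scale: str = "raw",
    na_tokens=DEFAULT_NA_TOKENS,
    log_transform: bool = True,
) -> ExpressionMatrix:
    """Read a delimited intensity matrix (first column feature ids, header samples).

    Cells equal to any ``na_token`` or empty become missing; on raw scale,
    values <= 0 also become missing (non-detection) and the matrix is
    log2-transformed unless ``log_transform=False``.
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=list(na_tokens),
        keep_default_na=False,
        dtype=str,
    )
    if df.shape[1] < 2:
        raise ValueError("matrix needs at least 2 sample columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups[:5]}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if scale == "raw":
        vals = df.to_numpy(dtype=float)
        vals[vals <= 0] = np.nan  # zero intensity = non-detection
        if log_transform:
            df = pd.DataFrame(np.log2(vals), index=df.index, columns=df.columns)
            return ExpressionMatrix(df, "log2")
        return ExpressionMatrix(pd.DataFrame(vals, index=df.index, columns=df.columns), "raw")
    return ExpressionMatrix(df, "log2")


def write_matrix(m: ExpressionMatrix, path) -> None:
    out = m.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="NA")


def read_annotation(path, matrix: ExpressionMatrix | None = None) -> FeatureAnnotation:
    """Read an annotation TSV (feature_id, peptide_sequence, charge, protein_id).

    Rows referencing features absent from ``matrix`` (when given) are skipped
    with a warning.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, na_values=[""], keep_default_na=False)
    df["charge"] = pd.to_numeric(df.get("charge"), errors="coerce")
    for col in ("peptide_sequence", "protein_id"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    if matrix is not None:
        known = set(matrix.feature_ids)
        unknown = ~df["feature_id"].isin(known)
        if unknown.any():
            warnings.warn(f"{int(unknown.sum())} annotation rows reference unknown features; skipped")
            df = df[~unknown]
    return FeatureAnnotation(df.reset_index(drop=True))


def read_groups(path, kind: str = "complex") -> GroupCatalog:
    """Read a group TSV with one member per row (group_id, protein_id)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    groups: dict[str, set] = {}
    for gid, pid in zip(df["group_id"], df["protein_id"]):
        groups.setdefault(str(gid), set()).add(str(pid))
    return GroupCatalog({g: frozenset(v) for g, v in groups.items()}, kind)


def read_design(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep=_sep_for(path), dtype=str))


def write_table(obj, path) -> None:
    """Write any of the companion objects (or a DataFrame) to delimited text."""
    sep = _sep_for(path)
    if isinstance(obj, ExpressionMatrix):
        write_matrix(obj, path)
    elif isinstance(obj, FeatureAnnotation):
        obj.table.to_csv(path, sep=sep, index=False)
    elif isinstance(obj, GroupCatalog):
        rows = [(g, p) for g, members in obj.groups.items() for p in sorted(members)]
        pd.DataFrame(rows, columns=["group_id", "protein_id"]).to_csv(path, sep=sep, index=False)
    elif isinstance(obj, SampleDesign):
        obj.table.to_csv(path, sep=sep, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=sep, index=False)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Completeness and filtering
# ---------------------------------------------------------------------------

def completeness_summary(m: ExpressionMatrix) -> dict:
    """Counts of missing cells, overall and per sample."""
    miss = m.missing_mask
    per_sample = {s: int(c) for s, c in zip(m.sample_ids, miss.sum(axis=0))}
    any_na = miss.any(axis=1)
    return {
        "n_features": m.n_features,
        "n_samples": m.n_samples,
        "n_missing_cells": int(miss.sum()),
        "fraction_features_with_any_na": float(any_na.sum() / m.n_features) if m.n_features else 0.0,
        "per_sample_counts": per_sample,
    }


def filter_by_na(m: ExpressionMatrix, max_na_fraction: float) -> ExpressionMatrix:
    """Keep features whose missing fraction is <= ``max_na_fraction``."""
    if not 0 <= max_na_fraction <= 1:
        raise ValueError("max_na_fraction must be in [0, 1]")
    frac = m.missing_mask.mean(axis=1)
    keep = np.flatnonzero(frac <= max_na_fraction + 1e-12)
    if keep.size == 0:
        raise ValueError(
            f"all {m.n_features} features exceed the NA threshold {max_na_fraction}"
        )
    return m.subset_features(keep)


def filter_by_cv(
    m: ExpressionMatrix,
    max_cv_percent: float,
    design: SampleDesign | None = None,
) -> ExpressionMatrix:
    """Drop features with a large coefficient of variation.

    CV is computed on raw-scale intensities over observed values only (CV on
    log values is not scale-meaningful).  With a design, a feature is removed
    only when its CV exceeds the threshold in *every* group, so genuinely
    regulated features survive.  Features with < 2 observed values have an
    undefined CV and are retained with a warning.
    """
    if max_cv_percent <= 0:
        raise ValueError("max_cv_percent must be > 0")
    raw = 2.0 ** m.values if m.scale == "log2" else m.values

    def cv_percent(block: np.ndarray) -> np.ndarray:
        n_obs = np.sum(~np.isnan(block), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(block, axis=1)
            sd = np.nanstd(block, axis=1, ddof=1)
        cv = np.full(block.shape[0], np.nan)
        ok = (n_obs >= 2) & (mean > 0)
        cv[ok] = 100.0 * sd[ok] / mean[ok]
        return cv

    if design is None:
        cv = cv_percent(raw)
        exceed = cv > max_cv_percent  # NaN compares False -> retained
    else:
        sample_pos = {s: i for i, s in enumerate(m.sample_ids)}
        exceed = np.ones(m.n_features, dtype=bool)
        for label in design.group_labels:
            cols = [sample_pos[s] for s in design.samples_of(label) if s in sample_pos]
            cv = cv_percent(raw[:, cols])
            exceed &= cv > max_cv_percent
    n_undef = int(np.sum(np.sum(~np.isnan(raw), axis=1) < 2))
    if n_undef:
        warnings.warn(f"{n_undef} features have < 2 observed values; CV undefined, retained")
    keep = np.flatnonzero(~exceed)
    if keep.size == 0:
        raise ValueError(f"all {m.n_features} features exceed CV {max_cv_percent}%")
    return m.subset_features(keep)
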