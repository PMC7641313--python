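"""Ground-truth masking experiment.

The benchmark extracts the fully-observed submatrix of a dataset, injects
artificial missing values at a chosen proportion, and later compares each
imputed value against the real value it replaced.  Two mechanisms:

* ``mcar`` -- cells are a uniform random sample without replacement of the
  whole grid (missing completely at random; the benchmark default).
* ``left_censored`` -- an MNAR extension: cells are drawn with probability
  proportional to a logistic function of negative intensity, so low-intensity
  cells are preferentially removed, emulating detection-limit censoring.

Masks never leave a feature or a sample with zero observed values (re-draw
rule; several imputers are undefined there), and the masked cell count is
exactly round(proportion x n_cells) with half-away-from-zero rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import derive_seed, round_half_away
from .data import ExpressionMatrix

__all__ = [
    "MaskSpec",
    "MaskedEvaluation",
    "complete_submatrix",
    "apply_mask",
    "mask_sweep",
    "pair_evaluation",
    "save_mask",
    "load_mask",
]

DEFAULT_SWEEP = tuple(np.round(np.arange(0.05, 0.7001, 0.05), 2))  # 14 proportions


@dataclass(frozen=True)
class MaskSpec:
    """Coordinates (row-major order) and provenance of one injected mask."""

    coordinates: tuple  # tuple of (feature_index, sample_index)
    proportion: float
    seed: int
    mechanism: str

    @property
    def n_masked(self) -> int:
        return len(self.coordinates)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        coords = np.asarray(self.coordinates, dtype=int).reshape(-1, 2)
        return coords[:, 0], coords[:, 1]


@dataclass
class MaskedEvaluation:
    """Original vs imputed values at the masked coordinates, aligned row-major."""

    y_o: np.ndarray
    y_i: np.ndarray
    feature_index: np.ndarray

    def __post_init__(self) -> None:
        self.y_o = np.asarray(self.y_o, dtype=float)
        self.y_i = np.asarray(self.y_i, dtype=float)
        self.feature_index = np.asarray(self.feature_index, dtype=int)
        if not (len(self.y_o) == len(self.y_i) == len(self.feature_index)):
            raise ValueError("y_o, y_i and feature_index must have equal length")


def complete_submatrix(m: ExpressionMatrix, min_features: int = 10) -> ExpressionMatrix:
    """Features with zero missing cells, order preserved."""
    keep = np.flatnonzero(~m.missing_mask.any(axis=1))
    if keep.size < min_features:
        raise ValueError(
            f"only {keep.size} complete features (< {min_features}); "
            "relax filtration or lower min_features"
        )
    return m.subset_features(keep)


def apply_mask(
    m: ExpressionMatrix,
    proportion: float,
    seed: int,
    mechanism: str = "mcar",
    censor_strength: float = 4.0,
    max_attempts: int = 100,
) -> tuple[ExpressionMatrix, MaskSpec]:
    """Inject exactly round(proportion x n_cells) missing cells into a complete matrix.

    For ``left_censored`` the inclusion weight is logistic(strength *
    (tau - x) / sd) with tau the intensity quantile at the masking
    proportion, so the mask concentrates on the low-intensity tail the way a
    detection limit would; ``censor_strength`` (default 4.0) sets how sharp
    the cut is.
    """
    X = m.values
    if np.isnan(X).any():
        raise ValueError("apply_mask requires a complete matrix")
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    if mechanism not in ("mcar", "left_censored"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    n, s = X.shape
    n_cells = n * s
    n_mask = round_half_away(proportion * n_cells)
    if n_mask < 1 or n_mask >= n_cells:
        raise ValueError(f"mask of {n_mask} cells is degenerate for a {n}x{s} matrix")

    flat = X.ravel()
    if mechanism == "left_censored":
        sd = float(np.std(flat)) or 1.0
        tau = float(np.quantile(flat, proportion))
        w = expit(censor_strength * (tau - flat) / sd)
        p = w / w.sum()
    else:
        p = None

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        idx = rng.choice(n_cells, size=n_mask, replace=False, p=p)
        rows, cols = np.unravel_index(idx, (n, s))
        if (np.bincount(rows, minlength=n) < s).all() and (np.bincount(cols, minlength=s) < n).all():
            break
    else:
        raise ValueError(
            f"could not draw a {proportion:.0%} mask leaving every feature and "
            f"sample partially observed after {max_attempts} attempts"
        )
    order = np.argsort(idx)  # row-major coordinate order
    rows, cols = rows[order], cols[order]
    masked = X.copy()
    masked[rows, cols] = np.nan
    spec = MaskSpec(
        coordinates=tuple((int(r), int(c)) for r, c in zip(rows, cols)),
        proportion=float(proportion),
        seed=int(seed),
        mechanism=mechanism,
    )
    return m.with_values(masked), spec


def mask_sweep(
    m: ExpressionMatrix,
    proportions=None,
    seeds=(0,),
    mechanism: str = "mcar",
    **kwargs,
) -> list[tuple[ExpressionMatrix, MaskSpec]]:
    """One independently drawn mask per (proportion, seed) pair.

    Default grid is 5%..70% in 5% steps (14 proportions).  Draws are
    independent across proportions (masks are not nested).
    """
    if proportions is None:
        proportions = DEFAULT_SWEEP
    proportions = list(proportions)
    if proportions != sorted(proportions):
        raise ValueError("proportions must be sorted ascending")
    out = []
    for p in proportions:
        for seed in seeds:
            child = derive_seed(seed, "mask_sweep", int(round(p * 1000)))
            out.append(apply_mask(m, p, child, mechanism, **kwargs))
    return out


def pair_evaluation(
    original: ExpressionMatrix,
    imputed: ExpressionMatrix,
    spec: MaskSpec,
    method_name: str = "?",
) -> MaskedEvaluation:
    """Align original and imputed values at the masked coordinates."""
    rows, cols = spec.index_arrays()
    y_o = original.values[rows, cols]
    y_i = imputed.values[rows, cols]
    if np.isnan(y_i).any():
        n_bad = int(np.isnan(y_i).sum())
        raise ValueError(f"method {method_name!r} left {n_bad} masked cells unimputed")
    return MaskedEvaluation(y_o=y_o, y_i=y_i, feature_index=rows)


def save_mask(spec: MaskSpec, m: ExpressionMatrix, tsv_path, json_path) -> None:
    """TSV of masked (feature_id, sample_id) plus a JSON sidecar for replay."""
    rows, cols = spec.index_arrays()
    fids, sids = m.feature_ids, m.sample_ids
    pd.DataFrame(
        {"feature_id": [fids[r] for r in rows], "sample_id": [sids[c] for c in cols]}
    ).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(
            {"proportion": spec.proportion, "seed": spec.seed, "mechanism": spec.mechanism},
            fh,
        )


def load_mask(tsv_path, json_path, m: ExpressionMatrix) -> MaskSpec:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    with open(json_path) as fh:
        meta = json.load(fh)
    fpos = {f: i for i, f in enumerate(m.feature_ids)}
    spos = {s: i for i, s in enumerate(m.sample_ids)}
    coords = sorted((fpos[f], spos[s]) for f, s in zip(df["feature_id"], df["sample_id"]))
    return MaskSpec(tuple(coords), float(meta["proportion"]), int(meta["seed"]), meta["mechanism"])
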