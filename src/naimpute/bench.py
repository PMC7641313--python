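"""End-to-end benchmark orchestration.

``run_benchmark`` wires the full workflow together: take a matrix, extract
its complete submatrix, inject an artificial mask, run a list of imputation
methods, score every result with the classic and (when annotation/catalogs
are present) proteomic criteria, and assemble the score table with ranks.
Both the CLI and the reproduction script drive this function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import derive_seed
from .criteria import CriterionScore, acc_oi, nrmse, pss_procrustes, sor
from .data import ExpressionMatrix, FeatureAnnotation, GroupCatalog
from .imputers import ImputerSpec, method_info, run_methods
from .masking import MaskSpec, apply_mask, complete_submatrix, pair_evaluation
from .proteomic import acc_charge, acc_complex, acc_pepprot, acc_ppi
from .ranking import PROTEOMIC_CRITERIA, ScoreTable, final_check

__all__ = ["BenchmarkResult", "run_benchmark", "DEFAULT_BENCH_METHODS"]

#: default benchmark battery: the fast tier
DEFAULT_BENCH_METHODS = (
    "zero", "minimum", "colmedian", "rowmedian",
    "mindet", "minprob", "pi", "qrilc",
    "svd", "mle", "impseq", "impseqrob",
    "knn", "seqknn", "lls", "grr",
)


@dataclass
class BenchmarkResult:
    score_table: ScoreTable
    original: ExpressionMatrix  # the complete submatrix (ground truth)
    mask: MaskSpec
    results: list
    failures: dict
    flags: dict = field(default_factory=dict)
    original_proteomic: dict = field(default_factory=dict)


def _proteomic_scores(m, ann, complexes, ppi) -> dict[str, CriterionScore]:
    out = {}
    if ann is not None:
        out["ACC_Charge"] = acc_charge(m, ann)
        out["ACC_PepProt"] = acc_pepprot(m, ann)
    if complexes is not None:
        out["ACC_Complex"] = acc_complex(m, ann, complexes)
    if ppi is not None:
        out["ACC_PPI"] = acc_ppi(m, ann, ppi)
    return out


def run_benchmark(
    matrix: ExpressionMatrix,
    methods=DEFAULT_BENCH_METHODS,
    proportion: float = 0.2,
    seed: int = 0,
    mechanism: str = "mcar",
    annotation: FeatureAnnotation | None = None,
    complexes: GroupCatalog | None = None,
    ppi_clusters: GroupCatalog | None = None,
    min_complete_features: int = 10,
    method_params: dict | None = None,
    weights: dict | None = None,
) -> BenchmarkResult:
    """Mask-impute-evaluate-rank on one matrix.

    ``proportion`` defaults to 0.2; pass the dataset's own missing fraction
    to mirror its NA prevalence.  Stochastic methods get per-method seeds
    derived from ``seed``.
    """
    method_params = method_params or {}
    original = complete_submatrix(matrix, min_features=min_complete_features)
    masked, mask = apply_mask(original, proportion, derive_seed(seed, "mask"), mechanism)

    specs = [
        ImputerSpec(
            name,
            params=dict(method_params.get(name, {})),
            seed=derive_seed(seed, "impute", name) if method_info(name).stochastic else None,
        )
        for name in methods
    ]
    results, failures = run_methods(masked, specs)

    evaluations = {
        res.method_name: pair_evaluation(original, res.matrix, mask, res.method_name)
        for res in results
    }
    sor_scores = sor(evaluations) if len(evaluations) >= 2 else {}
    orig_proteomic = _proteomic_scores(original, annotation, complexes, ppi_clusters)

    raw_rows, reason_rows = {}, {}
    for res in results:
        name = res.method_name
        scores: dict[str, CriterionScore] = {
            "NRMSE": nrmse(evaluations[name]),
            "ACC_OI": acc_oi(evaluations[name]),
            "PSS": pss_procrustes(original, res.matrix),
        }
        if name in sor_scores:
            scores["SOR"] = sor_scores[name]
        scores.update(_proteomic_scores(res.matrix, annotation, complexes, ppi_clusters))
        raw_rows[name] = {c: (s.value if s.value is not None else np.nan) for c, s in scores.items()}
        reason_rows[name] = {c: (s.reason or "") for c, s in scores.items()}

    raw = pd.DataFrame(raw_rows).T
    order = [c for c in ("NRMSE", "SOR", "ACC_OI", "PSS") + PROTEOMIC_CRITERIA if c in raw.columns]
    raw = raw[order]
    reasons = pd.DataFrame(reason_rows).T.reindex(columns=order, fill_value="")
    table = ScoreTable.from_scores(raw, reasons, weights=weights)
    flags = final_check(table.normalized) if len(raw) >= 2 else {}
    return BenchmarkResult(
        score_table=table,
        original=original,
        mask=mask,
        results=results,
        failures=failures,
        flags=flags,
        original_proteomic={c: s.value for c, s in orig_proteomic.items()},
    )
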