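"""Synthetic DIA-like dataset generator.

Emulates the hierarchical correlation structure that the proteomic criteria
assume, on the log2-intensity scale:

* protein base abundances ~ Normal(22, 2) (log2 of typical DIA intensities);
* per-sample protein signal = base + group effect (for DE proteins)
  + complex latent factor x loading + protein-specific noise, so proteins of
  one complex co-vary with correlation ~ ``within_complex_r``;
* peptide profile = protein signal + abundance offset + Normal(0, noise_sd),
  so peptides of one protein co-vary with correlation ~ ``within_protein_r``
  (``noise_sd`` is derived from that target unless given explicitly);
* charge-state profile = peptide profile + offset + Normal(0, noise_sd/2).

A companion missingness injector supports MCAR (uniform cells) and MNAR
(left-censored: inclusion probability proportional to a logistic function of
negative intensity around the matrix's 10th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import derive_seed, round_half_away
from .data import ExpressionMatrix, FeatureAnnotation, GroupCatalog, SampleDesign

__all__ = ["FixtureSpec", "SimulatedDataset", "generate_dataset", "inject_missingness"]


@dataclass
class FixtureSpec:
    """Study conditions for the generator (defaults mirror a 10 vs 10 DIA design)."""

    n_proteins: int = 200
    peptides_per_protein: tuple = (2, 4)
    charges_per_peptide: tuple = (1, 3)
    n_samples_per_group: int = 10
    n_groups: int = 2
    complex_count: int = 30
    complex_size: tuple = (3, 6)
    ppi_cluster_count: int = 40
    ppi_cluster_size: tuple = (2, 5)
    de_fraction: float = 0.1
    de_effect: float = 1.0  # log2 units
    base_mean: float = 22.0
    base_sd: float = 2.0
    sample_sd: float = 1.0  # per-sample biological variation (log2)
    within_protein_r: float = 0.8
    within_complex_r: float = 0.6
    noise_sd: float | None = None  # derived from within_protein_r when None
    peptide_offset_sd: float = 1.5
    charge_offset_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_protein_r", "within_complex_r"):
            r = getattr(self, name)
            if not 0 < r < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_groups != 2:
            raise ValueError("the generator models exactly 2 condition groups")

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        r = self.within_protein_r
        return self.sample_sd * float(np.sqrt((1 - r) / r))


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix  # complete, log2
    annotation: FeatureAnnotation
    complexes: GroupCatalog
    ppi_clusters: GroupCatalog
    design: SampleDesign
    truth: dict = field(default_factory=dict)


def _partition(rng, protein_ids, count, size_range, prefix):
    """Disjoint random groups of proteins."""
    shuffled = list(rng.permutation(protein_ids))
    groups = {}
    pos = 0
    for g in range(count):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if pos + size > len(shuffled):
            break
        groups[f"{prefix}{g:03d}"] = frozenset(shuffled[pos : pos + size])
        pos += size
    return groups


def generate_dataset(spec: FixtureSpec) -> SimulatedDataset:
    """Draw one complete dataset (matrix + annotation + catalogs + design + truth)."""
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_samples_per_group * 2
    sample_ids = [f"A{i + 1:02d}" for i in range(spec.n_samples_per_group)] + [
        f"B{i + 1:02d}" for i in range(spec.n_samples_per_group)
    ]
    group_b = np.array([0] * spec.n_samples_per_group + [1] * spec.n_samples_per_group)
    protein_ids = [f"P{i:04d}" for i in range(spec.n_proteins)]

    complexes = _partition(rng, protein_ids, spec.complex_count, spec.complex_size, "CPX")
    protein_complex = {p: g for g, members in complexes.items() for p in members}
    # PPI clusters overlap the complex structure (as hu.MAP clusters overlap
    # CORUM): each cluster is a random subset of one complex's members, so
    # cluster members share that complex's latent factor.
    ppi: dict[str, frozenset] = {}
    complex_ids = list(complexes)
    for g in range(spec.ppi_cluster_count):
        src = complexes[complex_ids[int(rng.integers(len(complex_ids)))]]
        size = min(int(rng.integers(spec.ppi_cluster_size[0], spec.ppi_cluster_size[1] + 1)), len(src))
        if size < 2:
            continue
        ppi[f"CL{g:03d}"] = frozenset(rng.choice(sorted(src), size=size, replace=False))

    n_de = round_half_away(spec.de_fraction * spec.n_proteins)
    de_proteins = list(rng.choice(protein_ids, size=n_de, replace=False)) if n_de else []
    de_sign = {p: (1.0 if i % 2 == 0 else -1.0) for i, p in enumerate(de_proteins)}

    lam = float(np.sqrt(spec.within_complex_r))
    complex_factor = {g: rng.standard_normal(n_samples) for g in complexes}
    noise_sd = spec.resolved_noise_sd

    values, feature_ids, ann_rows = [], [], []
    de_features = []
    for pid in protein_ids:
        base = spec.base_mean + spec.base_sd * rng.standard_normal()
        own = rng.standard_normal(n_samples)
        if pid in protein_complex:
            signal = lam * complex_factor[protein_complex[pid]] + np.sqrt(1 - lam**2) * own
        else:
            signal = own
        protein_profile = base + spec.sample_sd * signal
        if pid in de_sign:
            protein_profile = protein_profile + de_sign[pid] * spec.de_effect * group_b
        n_pep = int(rng.integers(spec.peptides_per_protein[0], spec.peptides_per_protein[1] + 1))
        for pep in range(n_pep):
            seq = f"{pid}_PEP{pep:02d}"
            pep_profile = (
                protein_profile
                + spec.peptide_offset_sd * rng.standard_normal()
                + noise_sd * rng.standard_normal(n_samples)
            )
            n_charge = int(rng.integers(spec.charges_per_peptide[0], spec.charges_per_peptide[1] + 1))
            charges = 2 + np.arange(n_charge)  # typical tryptic charge states
            for z in charges:
                fid = f"{seq}_z{z}"
                profile = (
                    pep_profile
                    + spec.charge_offset_sd * rng.standard_normal()
                    + (noise_sd / 2) * rng.standard_normal(n_samples)
                )
                values.append(profile)
                feature_ids.append(fid)
                ann_rows.append((fid, seq, int(z), pid))
                if pid in de_sign:
                    de_features.append(fid)

    matrix = ExpressionMatrix(
        pd.DataFrame(np.vstack(values), index=feature_ids, columns=sample_ids), "log2"
    )
    annotation = FeatureAnnotation(
        pd.DataFrame(ann_rows, columns=["feature_id", "peptide_sequence", "charge", "protein_id"])
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group_label": ["A"] * spec.n_samples_per_group + ["B"] * spec.n_samples_per_group,
            }
        )
    )
    truth = {
        "de_proteins": sorted(de_proteins),
        "de_features": sorted(de_features),
        "de_sign": {p: de_sign[p] for p in de_proteins},
        "effect": spec.de_effect,
        "noise_sd": noise_sd,
    }
    return SimulatedDataset(
        matrix=matrix,
        annotation=annotation,
        complexes=GroupCatalog(complexes, "complex"),
        ppi_clusters=GroupCatalog(ppi, "ppi_cluster"),
        design=design,
        truth=truth,
    )


def inject_missingness(
    m: ExpressionMatrix,
    mcar_fraction: float = 0.1,
    mnar_fraction: float = 0.0,
    mnar_strength: float = 4.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Remove cells MCAR (uniform) and/or MNAR (left-censored).

    MNAR cells are drawn without replacement with probability proportional to
    logistic(mnar_strength * (tau - x)) where tau is the matrix's 10th
    percentile, so large strength concentrates removal in the low-intensity
    tail.  Total missing count = round(mcar_fraction * n) + round(mnar_fraction * n).
    """
    X = m.values
    if np.isnan(X).any():
        raise ValueError("inject_missingness expects a complete matrix")
    n_cells = X.size
    n_mcar = round_half_away(mcar_fraction * n_cells)
    n_mnar = round_half_away(mnar_fraction * n_cells)
    if n_mcar + n_mnar >= n_cells:
        raise ValueError("requested missingness would empty the matrix")
    rng = np.random.default_rng(derive_seed(seed, "inject_missingness"))
    flat = X.ravel().copy()
    chosen = []
    if n_mnar:
        tau = float(np.quantile(flat, 0.10))
        w = expit(mnar_strength * (tau - flat))
        p = w / w.sum()
        chosen.append(rng.choice(n_cells, size=n_mnar, replace=False, p=p))
    if n_mcar:
        pool = np.setdiff1d(np.arange(n_cells), chosen[0] if chosen else np.empty(0, dtype=int))
        chosen.append(rng.choice(pool, size=n_mcar, replace=False))
    if chosen:
        idx = np.concatenate(chosen)
        flat[idx] = np.nan
    return m.with_values(flat.reshape(X.shape))
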