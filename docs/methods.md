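# Methods

## The benchmarking model

`naimpute` evaluates imputation by a masked-reference experiment. Because
real missing values have no ground truth, the benchmark (i) keeps only the
features observed in every sample, (ii) deletes a fraction *p* of those
cells artificially, and (iii) measures how well each method restores them.
The implicit assumption is that the complete features are representative
enough of the incomplete ones for relative method ranking — they are
typically more abundant, which is why the proteomic criteria (computable on
the whole matrix, not only on the complete part) complement the masked-cell
scores.

All computation is on log2 intensities. Raw-scale input is transformed on
ingest; zeros and negative values are treated as non-detections and become
missing before the transform. The log2 convention matters because
single-value methods (global minimum, down-shifted normals) are
scale-dependent, and because intensity data are approximately log-normal so
Gaussian machinery (EM, conditional means, t-tests) is only appropriate
after the transform.

### Masking mechanisms

* **MCAR** — cells are a uniform sample without replacement of the grid.
* **left_censored** — an MNAR stress test. Inclusion weight for cell value
  x is `logistic(strength · (τ − x) / sd)` where τ is the matrix intensity
  quantile at the masking proportion and `sd` the matrix standard
  deviation; `censor_strength` defaults to 4. Centering the logistic at the
  proportion-matched quantile makes the mask behave like a detection limit:
  almost all removed cells come from the low tail. (A logistic centered at
  the matrix mean, at any strength, removes mostly mid-intensity cells and
  is not censoring in any useful sense.)

The masked cell count is exactly `round(p · n_cells)` (half away from
zero). A mask is redrawn (up to 100 attempts) if it would leave any feature
or sample with zero observed values, since several imputers are undefined
there; this is a deliberate, documented deviation from pure uniform
sampling. Coordinates are stored in row-major order so the
original/imputed value vectors are reproducible.

## Criteria

### Classic

* **NRMSE** uses the sample variance (n−1 denominator) of the original
  values; one global score over all masked cells.
* **SOR** ranks methods per missing variable (feature) by per-variable
  NRMSE and sums the ranks; average ranks on ties. A variable with a single
  masked cell, or zero variance across its masked cells, ranks by squared
  error instead (the ordering semantics are unchanged; per-variable NRMSE
  is undefined there).
* **ACC_OI** is the Pearson correlation of original vs imputed values.
  Constant imputations have zero standard deviation and the score is
  reported as "no result" with a reason, not as a number — and such methods
  take the worst rank positions for that criterion.
* **PSS** extracts PCA sample scores (samples as observations, centered
  features, default 2 components) from the original and the imputed matrix
  and reports the residual sum of squares after optimally translating,
  rotating/reflecting and isotropically scaling the imputed configuration
  onto the original (full similarity Procrustes, via
  `scipy.linalg.orthogonal_procrustes`). PCA axis sign indeterminacy is
  absorbed by the rotation.

### Proteomic

Bottom-up quantification is redundant by construction: charge states of a
peptide, peptides of a protein, proteins of a complex or interaction
cluster should co-vary across samples. For each level, groups with ≥ 2
matched members contribute the mean Pearson correlation over all unordered
member pairs, and the criterion is the mean of group scores. The per-group
divisor is the pair count C(m, 2) — the printed group-ACC formulas in the
literature sometimes divide the pair sum by the member count m, which is
unbounded above 1 for m > 2; the pair-count divisor is used by default
because only it yields the bounded "average correlation" the criteria
describe (`divisor="m"` is available). Pairs where either member has zero
variance are skipped; correlations are pairwise-complete, so the reference
values can be computed on the un-imputed matrix as well.

For the complex/cluster criteria on peptide-level matrices, protein
profiles are first summarized as the mean of the top-3 most abundant member
log2 profiles (`aggregate="mean"` averages all members). For the
peptide-per-protein criterion, charge rows of one peptide sequence are
averaged into a single peptide profile first.

## Ranking

Normalized scores put the best method at 1: `value/max` for
higher-is-better criteria and `min/value` for lower-is-better ones (NRMSE,
SOR, PSS). Dividing lower-is-better scores by their maximum would award 1
to the *worst* method, so the min/value form is used; raw values are always
retained, and normalization is order-preserving, so ranks computed on raw
and normalized scores agree. Composite ranks are the weighted mean of
per-criterion ranks within a family (classic or proteomic; default weight
1, weight 0 removes a criterion), re-ranked; they are invariant to uniform
weight scaling. Methods missing a criterion share the trailing rank
positions (average of the worst slots), which conserves the rank sum.

The **final check** flags any criterion whose normalized score range across
methods is below a spread threshold (default 0.05) as non-discriminative.
The **targeted check** tabulates, per requested feature and method, the
observed range and each imputed value, flagging values outside the observed
min/max.

## Imputation methods — numerical choices

* Observed cells are restored bit-for-bit after every method; completeness
  is enforced centrally.
* **mindet**: per-sample q-quantile, q = 0.01 (q = 0 gives the sample
  minimum). **minprob**: Gaussian draws centered at that quantile with sd =
  `tune` × median per-feature sd (tune = 1). **pi**: per-sample
  `N(mean − 1.8·sd, (0.3·sd)²)`, the down-shifted-normal convention.
* **qrilc**: per sample, the uncensored normal is estimated by regressing
  observed order statistics on standard-normal quantiles. The observed
  order statistics are quantiles of the *truncated* distribution, so their
  plotting positions are mapped to full-distribution probabilities by
  reserving the censored mass (the sample's missing fraction) on the left;
  the fit uses the upper 75% of the observed distribution, and draws come
  from the fitted normal truncated above at the fitted quantile of the
  censored mass. Samples with < 5 observed values fall back to mindet with
  a warning. This is an approximation to the cited quantile-regression
  imputation, documented as such.
* **knn**: distances are root-*mean*-square differences over jointly
  observed samples (comparable across pairs with different joint support;
  no joint support → infinite distance). The k = 10 nearest features supply
  a 1/distance-weighted average; zero-distance neighbours get uniform
  weights (1/0 is undefined); distance ties break by input order;
  neighbours missing at a sample are skipped, and if none has a value there
  the feature's own mean is used.
* **seqknn**: features imputed in ascending-NA order against a pool that
  starts with the complete features and grows with each imputed feature.
* **lls**: the k = 10 complete features most |Pearson|-correlated with the
  target (over its observed samples) enter an intercepted linear fit solved
  by singular-value-truncated least squares (`rcond = 1e-8`); k is clamped
  to the number of complete features and to n_observed − 2. The
  pseudoinverse solve matters: the complete-feature pool is small and
  collinear at realistic missingness, and a plain normal-equation solve
  amplifies that collinearity into wild extrapolations.
* **svd**: missing cells start at feature means; rank-5 truncated SVD
  reconstruction rewrites only the missing cells until their relative
  change < 1e-2 (or 100 iterations; non-convergence returns the best
  iterate, flagged).
* **mle**: EM for an `n_samples`-dimensional Gaussian with features as
  i.i.d. observations, grouped by missingness pattern; ridge 1e-6 on the
  covariance diagonal each M-step; tolerance 1e-6 on imputed-cell change,
  max 500 iterations. Diagnostics expose the fitted mean and covariance.
* **impseq / impseqrob**: location/scatter seeded from the complete
  features (falling back to the mean-filled matrix when fewer than
  n_samples + 1 are complete, with a warning — strictness here would make
  the method unusable at realistic missingness); incomplete features
  processed in ascending-NA order, filled with the Gaussian conditional
  mean, then folded into running Welford moments. The robust variant uses
  median location and 3-MAD winsorized updates.
* **chained engine** (`grr`, `irm`, `mice_norm`, `mice_cart`, `rf`): mean
  initialization, then n_iter rounds in which each incomplete feature is
  regressed across samples on all other features (BayesianRidge with a
  posterior noise draw / regression tree / random forest / Huber / Ridge —
  the ridge engine is the stand-in for generalized ridge regression, whose
  exact published formulation is not reproduced here). `n_iter = 0` returns
  the mean-imputed matrix. Engine failure on a feature falls back to the
  feature mean for that round with a warning. These scale quadratically in
  the feature count and form the slow tier.
* **bpca / trknn / gms** are plugin slots: their algorithms belong to
  external packages and can be registered at run time
  (`register_plugin(name, func)`) without touching core code.

Reference-package defaults are adopted where choices were open: KNN/LLS
k = 10, SVD rank 5, MinDet/MinProb q = 0.01, PI shift 1.8 / width 0.3. Every
one is an explicit keyword argument.

## Differential expression

Equal-variance two-tailed Student's t (Welch by flag), BH correction across
all features, significance = BH p < 0.05 AND |log2FC| > 0.585 (log2 of a
1.5-fold change, to the conventional printed precision). log2FC is the
first design-group mean minus the second, fixed by the design file's label
order. Zero variance in both groups yields p = 1 when the means agree and
p = 0 otherwise. The subsampling simulation draws k replicates per group
without replacement, n_repeats times (default 100), and reports per-repeat
significant counts plus per-feature medians of p, BH p and log2FC; the
median-based volcano uses median p and median FC independently, accepting
that the pair may not co-occur in any single repeat. Gold-standard overlap
is the Jaccard index between the full-data significant set and the
median-based subsample calls.

## The synthetic generator

`FixtureSpec` defaults define the study conditions: 200 proteins with 2–4
peptides each at 1–3 charge states (~1200 features), 10 vs 10 samples,
log2 base abundance N(22, 2), per-sample biological variation sd 1.0,
within-protein peptide correlation 0.8 (peptide noise derived as
`sd·√((1−r)/r)`), 30 complexes of 3–6 proteins sharing a latent factor with
within-complex correlation 0.6, and interaction clusters drawn as random
subsets of complexes (as PPI clusters overlap complexes in curated
resources). 10% of proteins carry a ±1 log2-unit group effect. These
settings put the original-matrix coherence criteria in the informative
mid-range (ACC_Charge ≈ 0.95, ACC_PepProt ≈ 0.78, ACC_Complex/PPI ≈ 0.5)
where methods separate. Missingness injection supports MCAR plus MNAR with
a logistic weight around the 10th intensity percentile (strength 8 by
default in tests of the MNAR path).

What the generator does *not* emulate: instrument-specific missingness,
batch effects, retention-time drift, non-Gaussian heavy tails,
identification-level FDR, shared peptides between proteins. Passing tests
on this generator show the machinery is correct and that method rankings
behave as the theory predicts under clean hierarchical correlation — not
that any particular method is best for a given real dataset; that is what
running the benchmark on one's own matrix is for.

## Problem sizes in the test suite and reproduction script

The ordering and concordance checks run the default 200-protein fixture at
25 and 20 seeds respectively (win thresholds 23/25 and 21/25, i.e. the 95%
and 90% proportions at those replicate counts); the DE calibration uses 20
null seeds and 20-repeat subsampling; the reproduction script runs one full
benchmark plus a 100-repeat subsampling simulation and completes in well
under a minute. The script's DE section uses a strongly regulated condition
(4-fold protein effects) because the default ±2-fold effect against ~1.2
log2 units of feature-level noise has essentially no BH power at 1200
features — an honest but uninformative demonstration.

## Known limitations

* The benchmark scores methods on the complete (more abundant) submatrix;
  extrapolation to low-abundance features relies on the proteomic criteria.
* QRILC and GRR are approximations to their cited formulations.
* The chained-equations tier is O(n_features²) per iteration and is meant
  for a few thousand features at most.
* Group catalogs are consumed as plain TSV; curation, licensing and ID
  mapping of complex/PPI resources are the user's responsibility.
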