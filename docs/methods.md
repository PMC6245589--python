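# Methods

## The classification framework

`chromstab` addresses binary phenotype classification (e.g. responder vs
non-responder to first-line chemotherapy) from additively coded SNP
genotypes plus clinical covariates, in the regime where features number
in the thousands to millions and samples in the low hundreds with strong
class imbalance.

The central difficulty is that no classifier can be tuned on all
chromosomes at once at that dimensionality without either heavy
univariate pre-filtering (which is exactly what the framework is meant
to improve on) or rampant over-fitting. The framework therefore
partitions the genome by chromosome, runs a fully tuned pipeline per
chromosome (*partial analysis*), and promotes to a genome-wide *final
model* only features whose selection is **stable** under subsampling of
a held-out stability set.

### Pipeline

Each pipeline has six stages, applied strictly in fit/transform
discipline (statistics estimated on fitting data are frozen and reused
on any other data):

1. **Mean imputation** of missing genotype codes, per column.
2. **Zero-variance filter** — drops columns constant on the fitting data.
3. **Standardization** to zero mean, unit population variance.
4. **Feature selection**, one of:
   - `anova` — one-way F-test filter keeping the ⌈p·ncol⌉ smallest
     p-values (ties broken by column order);
   - `rfe_lr` — recursive feature elimination wrapping an L1 logistic
     regression (C = 1); each round removes the step-fraction of
     current features with smallest |coefficient|;
   - `rlr_l1` — embedded selection keeping features with L1 logistic
     |coefficient| ≥ 10⁻¹⁰; C is grid-searched over
     {100, 500, 1000, 1500, 5000, 10000}.
5. **Resampling** of the *training data only*: none, random
   down-sampling of the majority to the minority size, random
   up-sampling of the minority with replacement, or SMOTE (synthetic
   minority points drawn uniformly on segments between a minority
   sample and one of its k = 5 nearest minority neighbours; k is
   reduced when the minority is smaller than 6). Validation and test
   data always keep the original class distribution.
6. **Classifier**: linear SVM (C ∈ {0.001 … 1000}), random forest
   (n_estimators ∈ {30 … 2999}), or k-NN (k ∈ {5, 20, 35, 50}).

Hyper-parameters are tuned by stratified, seeded 5-fold CV grid search
maximizing class-support-weighted F1 (2PR/(P+R) per class, weighted by
class support); ties go to the earlier grid point in declared order.
Within each fold all six stages are fit on the training folds alone, so
no validation-fold statistic (imputation mean, scaling, selection,
resampled rows) can leak into the scored model.

### Stability selection and merge

For each chromosome, S stratified subsamples of ⌈T·n⌉ stability-set
samples are drawn without replacement (defaults S = 100, T = 0.8); the
partial model's preprocessing and feature-selection stages are refit on
each with the partial model's frozen best hyper-parameters, and a
feature's stability score counts the refits whose support contains it.
Choices made here:

- **Frozen hyper-parameters.** Refitting means re-estimating stage
  statistics and the selection, not re-tuning: re-running the grid
  search per subsample would multiply cost by S and measures grid
  behaviour rather than selection stability.
- **Stratified subsamples.** With 71 stability samples and T = 80%, an
  unstratified draw can lose the minority class entirely; draws are
  stratified by the same largest-remainder allocation used for
  splitting.
- **The classifier is not refit during scoring** — the score depends
  only on the feature-selection support, so fitting a classifier per
  subsample would be wasted work.
- Features dropped by a refit's variance filter count as not selected;
  features a chromosome never sees score 0.

Features with score ≥ W (default W = 100 — selected in *every* refit,
deliberately restrictive) are merged across chromosomes, in chromosome
then column order; covariate columns contributed by several chromosome
views are deduplicated. The same pipeline configuration is re-tuned on
the merged training view and evaluated once on the merged test view.

The stability filter is applied outside any outer CV loop, so the merge
introduces a selection bias into final-model evaluation; using a
stability set disjoint from both training and test limits but does not
remove it. The framework documents this rather than correcting it (no
nested outer CV).

### Splitting arithmetic

Split part sizes are round-half-away-from-zero of n·fraction; the
per-class composition follows the largest-remainder rule (ties toward
the earlier class). On a 178-sample cohort with 137:41 classes this
gives test = 36 (28 + 8), preliminary = 142, then train = stability =
71 — matching the reference cohort's printed sizes exactly. A plain
per-class round-half-away would give a 35-sample test set; the
largest-remainder rule is what keeps both the total and the
stratification correct.

### Feature selection fractions and scale

The FS stage keeps 2% of features per chromosome during partial
analysis (RFE step 4%) and 10% during the final analysis (step 10%).
These fractions are calibrated for genome-scale inputs, where a merged
set holds hundreds to thousands of SNPs. On desk-scale synthetic
cohorts the merged set may hold fewer than a dozen features, and a 10%
final keep collapses it to a single column, degenerating the final
model into a majority-class predictor. The fractions are therefore
exposed (`fs_fractions` argument / config key); small-scale runs,
including the parameter-recovery study in `scripts/acceptance.py`, set
the final keep fraction to 1.0 — at that scale the stability threshold
already performed the final selection. Defaults are unchanged.

### Covariates

Clinical covariates (gender, smoker status, ECOG performance, histology,
treatment, arm) ride along as extra numeric columns in both each
chromosome's view and the merged view (configurable). They pass through
the same variance filter and selection as SNPs — they are not exempt —
and SNP-only accounting is used wherever features are counted or
intersected with the catalog.

## Synthetic cohorts

The generator emulates the statistical structure the framework assumes:

- **Genotypes** are sampled under Hardy-Weinberg equilibrium at
  per-SNP MAFs drawn uniformly from [0.01, 0.5] by default; each of two
  haplotypes carries the minor allele with probability MAF.
- **LD blocks** (optional) share a latent Gaussian per haplotype with
  compound-symmetric correlation ρ, thresholded at the MAF quantile —
  marginal frequencies are preserved exactly while neighbours become
  correlated. This is a convenience model: real LD decays with
  distance and is shaped by recombination and demography, none of which
  is emulated, and there is no population structure or coalescent
  realism. Passing tests therefore demonstrate the *framework's*
  correctness and power at the simulated signal strength, not
  performance on any real cohort.
- **Covariates** follow the marginal frequencies of a typical advanced
  NSCLC trial table (78% male, 94% smokers, ECOG mostly 0–1, etc.).
- **Phenotypes** follow a logistic model over planted causal SNPs
  (log-odds per minor allele) and optional covariate effects. The
  intercept is calibrated by bisection *on the realized class-1 count*
  for one fixed uniform draw, so a 178-sample cohort targeted at 41/178
  lands on 41 ± 1 rather than merely in expectation; an explicitly set
  intercept skips calibration. Defaults reproduce the emulated study
  conditions: n = 178, 22 autosomes, class-1 fraction 41/178, MAF ≥
  0.01, no missingness (configurable rate for exercising the imputer).

Null cohorts (no causal SNPs, no covariate effects) have labels
independent of all features by construction and drive the leakage and
permutation tests.

## Numerical and degenerate-input choices

- Standardization uses population (ddof = 0) scaling; zero-variance
  columns at standardization are an error (the variance filter must
  run first); an all-constant matrix yields an empty support with a
  warning, and a pipeline with empty support predicts the majority
  class during CV scoring.
- L1 logistic fits use liblinear (tol 10⁻⁶, max_iter 1000, retried at
  10000 before erroring on non-convergence).
- ANOVA p-values of NaN (degenerate columns) are treated as 1.
- Zero-support classes in evaluation yield 0 metrics with a warning,
  never an exception; the confusion matrix is stored so every reported
  metric is recomputable.
- Determinism: one master seed drives splitting, CV folds, resampling,
  stability draws and classifiers; per-experiment and per-chromosome
  seeds are derived through `numpy.random.SeedSequence`, so a repeated
  run writes byte-identical stability TSVs and report JSONs.
- Unsigned ranking sources (ANOVA p-values; RF importances without a
  selector coefficient) emit sign "." rather than fabricating a
  direction. RF importance is mean impurity decrease.
- GWAS-Catalog records keep associations with p < 10⁻⁶, drop multi-SNP
  interaction entries, and deduplicate to unique (chromosome, position,
  trait) triples keeping the first occurrence. Trait matching is exact
  (case-sensitive, whitespace-normalized) against shipped editable
  vocabularies; intersections require an explicitly declared, matching
  genome build on both sides (no liftover). Both position- and
  rsid-based intersection modes are provided.

## Problem sizes in the test suite and acceptance script

Simulated cohorts in the test suite use 2–22 chromosomes of 10–200
SNPs, n = 120–2000, and S between 2 and 100 — chosen so the whole suite
and the acceptance script each run in minutes on a single CPU. The
parameter-recovery study (n = 2000, 22 × 200 SNPs, 10 planted causal
SNPs at β = log 2, MAF 0.3, ANOVA + no sampling + linear SVM, S = 100,
T = 0.8, W = 100) is the package's standard power check: planted SNPs
should dominate the stability-score distribution and the final model
should clearly beat a 20-permutation label null.

## Known limitations

- The stability-filter selection bias described above is documented,
  not corrected.
- Multi-allelic variants, sex chromosomes, phasing and genotype
  imputation from raw array intensities are out of scope; VCF input
  must be biallelic, diploid and autosomal.
- The LD model is marginal-preserving but structurally naive (see
  above).
- Parallelism is a single-node worker pool over chromosomes
  (`--jobs`); distributed execution is out of scope.
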