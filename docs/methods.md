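# Methods

`epmet` implements a biomarker-discovery analysis for early-pregnancy
viability: separating live normally-sited pregnancy (LNSP) from pooled
adverse outcomes (CAO = miscarriage + PUL + tubal ectopic) using binned
serum ¹H NMR metabolite signals, plasma β-hCG and progesterone, and
clinicodemographics. This note records the statistical model behind each
stage, the defaults and why, what the synthetic cohort does and does not
emulate, and the design choices made where the design was genuinely open.

## Synthetic cohort (`epmet.simulate`)

The generator produces the *study conditions* the analysis assumes.

**Cohort.** Four outcome groups, default 146 LNSP / 77 miscarriage /
42 PUL / 51 tEP. Hormones are log-normal per group with (μ, σ) solved
analytically from the published group median m and IQR:
σ = asinh(IQR/2m)/z₀.₇₅, μ = ln m. This matches both the median and the
IQR exactly in population and respects positivity and right skew
(β-hCG medians 9893/607/100/859 U/L; progesterone 57/25/12/25 nmol/L).
Age is truncated normal (≥18 y, the inclusion criterion) with SD =
IQR/1.349; BMI log-normal from median/IQR; gestational age discrete
uniform on 4–10 completed weeks (only a median (IQR) of 6 (2) is
published, and ≤10 weeks is the inclusion bound); smoking, parity and
ethnicity Bernoulli at the published group rates.

**Spectra.** Each of 32 metabolites (named after the serum metabolites
typically annotated in CPMG spectra, with MSI level and HMDB accession)
emits `bins_per_metabolite = 3` bins; 70 bins stay unannotated. On the
log₂ scale a bin is

    baseline_b + scale_b · ( d_m·1[LNSP] + √ρ_m·z_im + √(1−ρ_m)·ε_ijb )
    + batch_effect(batch_i, b) + dilution_i

with `z` the shared metabolite latent, so sibling bins correlate ρ_m
(default 0.9; a per-metabolite sequence is accepted, because bins in
overlapped spectral regions integrate less cleanly than isolated peaks),
and a planted metabolite's every bin is shifted by the configured
standardized effect d_m relative to its biological SD. Nine metabolites
are planted by default at |d| 0.3–0.8, signed by the physiology of early
gestation (glutamate and phenylalanine higher in viable pregnancy;
acetate, alanine, arginine, glutamine higher in CAO). Batch effects are
additive per bin per batch on the log scale (SD 0.3 log₂ units, 3
batches) — a location-shift model, matching what the correction stage
removes; dilution is a per-sample multiplicative factor (log-scale SD
0.15). A random 1% of cells has a baseline offset subtracted to force
nonpositive values (binning artifacts); FWHM is N(1.1 Hz, 0.08) with 3%
contamination shifted +0.8 Hz so the QC filter has work to do.

Realized sibling correlations are slightly below ρ because batch and
dilution noise are unscaled; the planted standardized effect is d
relative to biological variation and is recovered after the batch and
dilution stages remove their components. What the generator does *not*
emulate: peak shapes, chemical-shift drift, heteroscedastic
technical error, missingness mechanisms tied to intensity, or
correlations between metabolites. Passing tests therefore demonstrate
that the machinery behaves correctly under its own model assumptions,
not that it will achieve any particular accuracy on patient data.

## Preprocessing (`epmet.preprocess`)

Fixed order: QC filter → nonpositive replacement → CRS reduction → PQN +
log₂ → batch correction. Each stage logs samples/bins in and out.

* **QC** (`k_sd = 2`): keep samples with FWHM ≤ mean + 2·SD, one-sided —
  broad lines violate minimum reporting standards, narrow lines do not.
* **Replacement** (`factor = 0.2`): nonpositive cells become ⅕ of the
  bin's minimum positive value; a bin with no positive value is an
  error naming the bin.
* **CRS.** Per-bin score = mean Pearson correlation with sibling bins of
  the same metabolite; single-bin metabolites score 1 by convention and
  always pass. Scores are computed on log₂ intensities (association of
  log-normal intensities is linear on the log scale; raw-scale Pearson
  is attenuated in proportion to each bin's dynamic range), while the
  matrix itself stays raw until the PQN stage, keeping the reduction
  ahead of normalization in the pipeline order. Global passing score =
  median − SD of the per-metabolite best scores over *multi-bin*
  metabolites (the conventional 1.0 of single-bin metabolites would
  inflate the threshold). A passing metabolite keeps only its best bin;
  a failing one keeps all bins (flagged lower-confidence); unannotated
  bins are always kept. Spearman and a frozen threshold are config
  options. Note the threshold is relative by construction: it marks the
  low outliers of whatever score distribution the data produce, so in a
  perfectly homogeneous matrix ~one in six metabolites must fail; "all
  pass" scenarios require genuine score heterogeneity.
* **PQN.** Reference = per-bin median over samples (no pre-diagnosis
  control group exists to prefer); dilution factor = median over bins of
  sample/reference; divide, then log₂. Given a fixed reference the
  normalized profile is exactly invariant to a sample's dilution level;
  re-estimating the reference from normalized data perturbs re-computed
  factors only by median-estimation noise (≲5% at 20+ bins).
* **Batch correction.** Per-bin model with batch one-hots plus preserved
  covariates (default: the outcome label, so biological signal is not
  absorbed); data standardized by the per-bin residual SD; per-batch
  per-bin location (γ) and scale (δ²) estimated and shrunk toward their
  across-bin moments — normal prior for γ, moment-matched inverse-gamma
  for δ² — by the standard fixed-point iteration; effects removed, grand
  means and covariate effects restored. `standardize` mode (no
  shrinkage) reduces exactly to per-bin per-batch standardization to the
  pooled moments and serves as the closed-form oracle in tests; `none`
  is a pass-through. Batches of one sample are an error (scale
  inestimable). The EB residual on a batch shift is ∝ δ²/(n_i·τ²), so
  removal is complete only insofar as true across-bin shift variance
  exists.
* **Fit/transform.** `Preprocessor` freezes every data-driven parameter
  (QC threshold, per-bin minimum positives, kept bins, PQN reference,
  batch adjustments) on a discovery set and applies them unchanged to
  validation samples. For held-out samples the batch transform centers
  on the per-bin grand mean without covariate contributions (outcomes
  are unknown at prediction time); since δ* ≈ 1 after shrinkage the
  distortion is negligible.

## Univariate statistics (`epmet.stats`)

Cohort description: continuous variables as median (IQR) per group with
Kruskal–Wallis; categoricals as n (%) with chi-squared (no continuity
correction by default, matching the generic test; Yates available);
Dunn's rank post-hoc with BH adjustment across pairs. Spearman screens
relate gestational age, β-hCG and progesterone within each group.

Differential abundance fits one fixed-effect linear model per bin,
`intensity ~ group + age + BMI + gestational age` (no random effects: no
grouping factor exists in a single-visit design; these covariates are
the ones that explain appreciable spectral variance, which
`covariate_variance_screen` quantifies as per-bin single-covariate R²).
Residual variances are moderated by empirical Bayes: s²₉ are modeled as
scaled inverse-χ²(d₀, s₀²); hyperparameters are moment-matched on
log s²₉ using the exact moments of log-χ² (digamma/trigamma, Newton
inversion of trigamma), giving

    s²_post = (d₀·s₀² + df·s²₉)/(d₀ + df),   t = β̂/(SE·s_post/s) on d₀+df df.

d₀ = 0 recovers ordinary t exactly; d₀ = ∞ shares one variance. The
implementation is validated against the Bioconductor reference
implementation on a fixture via Rscript. BH step-up is implemented
directly (NaN p-values are excluded from the ranking and propagate).

## Feature selection (`epmet.selection`)

**Split.** Stratified by outcome; per-stratum validation counts are
floor(f·n_s) with largest-remainder top-up to floor(f·n) total, so
146/77/42/51 at f = 0.2 gives exactly 253/63. Strata smaller than 2 stay
in discovery with a warning.

**Gate.** Features with BH q < 0.05 on the discovery set proceed;
hormones and demographics never pass through the gate — they enter
models by block configuration.

**Stability selection.** Ten outer folds (stratified); in each fold's
90% training part, 100 rounds of LASSO; each round re-randomizes only
the internal 5-fold cross-validation that picks λ from a log-spaced
100-point grid descending from the data-driven λ_max = max|Xᵀ(y−ȳ)|/n to
λ_max·10⁻³ (the penalized fit itself is deterministic, so round-to-round
variation flows solely through fold assignment). λ rule: `1se` (largest
penalty within one SE of the CV minimum; `min` available). A feature is
selected in a round iff its coefficient is nonzero; passes a fold iff
its round frequency is ≥ 0.80; enters the final set iff it passes
strictly more than 8 folds. The interpretation of the two-clause rule is
conjunctive and fold-wise; both thresholds are configurable.

The round-level selector defaults to the Gaussian LASSO on the 0/1
label (`family="gaussian"`), solved by a compiled Gram-form coordinate
descent with warm starts along the path (`epmet._lasso`, verified
against `sklearn.linear_model.lasso_path` to machine precision in
tests). For support recovery on standardized features the Gaussian and
binomial LASSO select the same strong features, and the Gaussian path
solves all 100 penalties in one sweep — the procedure runs ~1000
penalized CV searches per stability run, which an L1-logistic inner loop
(`family="binomial"`, available and cross-checked) makes two orders of
magnitude slower. Class imbalance (146 vs 170) is left unweighted by
default; weighting is a config option.

Within a round, standardization is computed once on the fold's training
part rather than re-estimated inside each internal CV split; at these
fold sizes the difference is far below the selection thresholds.

## Predictive models (`epmet.modeling`)

Variable blocks: `metabolites` (stability-selected bins), `hormones`
(β-hCG, progesterone), `demographics` (age, gestational age, BMI); the
six standard combinations form the reporting battery. Random forest
(500 trees, otherwise library defaults, logged seed) or unpenalized
logistic GLM; LNSP is the positive class; decision rule is the model
default (majority vote — no tuned threshold is assumed). Metrics come
from the validation confusion matrix: accuracy with exact binomial
(Clopper–Pearson) 95% CI — interior bounds by the α/2 beta-quantile
identity, boundary cases one-sided at full α, so a perfect score on n
has lower bound α^(1/n) — sensitivity, specificity, PPV, F1, and AUROC
as the midrank Mann–Whitney statistic U/(n₁n₀). Single-class validation
sets yield NaN sensitivity or specificity with a warning. PCA score
plots use unit-variance scaling (mixed-unit inputs); zero-variance
variables are dropped with a warning.

## Pipeline (`epmet.pipeline`, `epmet.cli`)

One YAML config drives all stages; a single root seed expands into
per-stage seeds; the manifest records the config snapshot, stage seeds,
SHA-256 of every artifact and per-stage counts, and suffices to re-run
bit-identically. Strict leakage mode (default) draws the split right
after sample-level QC (the FWHM rule depends on no outcome information)
and estimates all preprocessing on discovery only; `pooled`
estimates on the full matrix before splitting. Every excluded sample is
logged with the rule that excluded it.

## Numerical choices

* Coordinate descent: tol 1e-9 on the max coefficient change, exact
  zeros from soft thresholding; λ grid descending for warm starts.
* Trigamma inversion: Newton from x₀ = 0.5 + 1/y, tol 1e-10.
* EB batch fixed point: tol 1e-5, ≤200 iterations; variances floored at
  1e-12 before square roots.
* CRS tie-break: equal scores resolve to the lexicographically larger
  bin id (deterministic).
* Kruskal–Wallis on all-identical values is reported as p = 1.

## Test and simulation scale

The suites run the full chain at the study's cohort size (n = 316) with
20 seeds for the stochastic recovery/calibration checks, and smaller
cohorts (n ≈ 130) with reduced round counts for pipeline determinism
tests; these sizes were chosen so a complete run stays in the minutes
range on a single core while keeping binomial noise on per-seed success
fractions well below the asserted margins.

## Known limitations

* The CRS metric is a reconstruction from its description (mean sibling
  correlation, best-bin representative, median−SD threshold); the
  original in-house scoring may differ in detail, so annotation-count
  outcomes are treated as data-dependent, not as fixed targets.
* The moderated model uses fixed effects only; designs with repeated
  measures would need genuine mixed models.
* Under the generator's conditions with nine planted signals at d = 0.8
  and a 63-sample validation set, the Bayes-optimal accuracy is ≈ 0.885
  with a per-seed binomial SD ≈ 0.04, so validation accuracies of a
  metabolite-only forest concentrate around 0.84 and single-seed
  accuracy thresholds near 0.85 are met only in roughly half the seeds —
  an intrinsic ceiling of the conditions, not a fittable property.
* Batch correction assumes additive location/scale batch effects on the
  log scale; monotone distortions are out of scope.
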