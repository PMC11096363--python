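# epmet — early-pregnancy viability biomarkers from serum NMR metabolomics

Up to 30% of pregnancies present in the first trimester with pain or
bleeding, and clinicians must rapidly separate a **live normally-sited
pregnancy (LNSP)** from outcomes that will not progress — miscarriage,
pregnancy of unknown location (PUL) and tubal ectopic pregnancy (tEP),
pooled here as **combined adverse outcomes (CAO)**. `epmet` is a tested,
reusable implementation of a machine-learning biomarker-discovery
pipeline for this problem: it takes a binned ¹H NMR serum intensity
table, plasma β-hCG and progesterone, and clinicodemographics, and
produces validated classifiers of LNSP vs CAO, with a synthetic-cohort
module standing in for patient data so every stage is testable offline.

## The pipeline

1. **QC** — spectra whose alignment-peak FWHM exceeds the cohort mean by
   more than 2 SD are excluded.
2. **Nonpositive replacement** — each nonpositive bin intensity is
   replaced by ⅕ of the bin's minimum positive value.
3. **CRS reduction** — a metabolite emitting several redundant bins is
   collapsed to its most representative bin. Each bin's *correlation
   reliability score* is its mean Pearson correlation with sibling bins
   (log scale); a metabolite passes when its best score reaches the
   global threshold `median − SD` of the per-metabolite best scores,
   otherwise all of its bins are kept at lower annotation confidence.
4. **Normalization** — probabilistic quotient normalization (per-sample
   division by the median quotient against the per-bin median reference)
   followed by log₂.
5. **Batch correction** — parametric empirical-Bayes location/scale
   adjustment per bin per batch (outcome label preserved as covariate).
6. **Differential abundance** — per-bin linear models
   `intensity ~ group + age + BMI + gestational age`, residual variances
   moderated by an empirical-Bayes scaled inverse-χ² prior
   (s²₉ → (d₀s₀² + df·s²₉)/(d₀+df)), Benjamini–Hochberg FDR.
7. **Stability selection** — signals at 5% FDR enter a fold-wise LASSO
   consensus: 10 outer folds; in each fold's 90% training part, 100
   rounds of penalized selection with a freshly randomized internal CV
   choosing λ (1-SE rule); a feature passes a fold at ≥80% round
   frequency and is selected when it passes more than 8 folds.
8. **Models** — random forests (500 trees) on six variable blocks
   (metabolites / hormones / demographics and combinations), trained on
   a stratified 80% discovery set and evaluated on the held-out 20%
   validation set: accuracy with exact Clopper–Pearson 95% CI,
   sensitivity, specificity, PPV, F1 and midrank Mann–Whitney AUROC.

By default every data-driven preprocessing parameter is estimated on the
discovery samples only and applied frozen to the validation samples
(`--strict-leakage`); `--pooled-estimation` estimates them on the pooled
matrix before splitting.

## Worked example

```sh
epmet run-all --seed 7 --outdir runs/demo
```

simulates a 316-participant cohort (146 LNSP / 77 miscarriage / 42 PUL /
51 tEP, hormone distributions calibrated to published group medians and
IQRs), runs every stage and writes `report.md`. On this synthetic cohort
the run prints, among others:

```
stages.simulate.counts:   {samples: 316, bins: 166, annotated_bins: 96,
                           annotation_rate_pct: 57.8}
stages.preprocess.counts: {qc_excluded: 7, discovery: 248, validation: 61,
                           bins_after_crs: 108}
stages.stats.counts:      {bins_tested: 108, significant_5pct_fdr: 4}
stages.select.counts:     {gated: 4, selected: 4}
```

i.e. 7 spectra failed the FWHM rule, the redundancy reduction kept 108
of 166 bins, 4 bins were significant at 5% FDR on the discovery set and
all 4 survived the stability consensus; `metrics.csv` then holds one
Table-style row per variable block with validation accuracy and its
exact binomial CI. (The default generator plants nine discriminative
metabolites with |d| between 0.3 and 0.8, so only the stronger ones are
expected to survive selection in any one run.)

Library use mirrors the CLI: `epmet.simulate.generate_cohort` /
`generate_spectra`, `epmet.preprocess.Preprocessor`,
`epmet.stats.fit_moderated`, `epmet.selection.stability_select`,
`epmet.modeling.run_model_battery`.

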