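"""Synthetic early-pregnancy cohort and binned serum NMR spectra.

The downstream analysis (redundancy reduction, normalization, batch
correction, differential abundance, stability selection, classification)
assumes a specific statistical structure in its input:

* four final pregnancy outcomes — live normally-sited pregnancy (LNSP),
  miscarriage, pregnancy of unknown location (PUL) and tubal ectopic
  pregnancy (tEP) — with strictly positive, right-skewed plasma hormone
  levels whose group medians and IQRs differ sharply;
* a binned 1D 1H spectral intensity table in which each annotated
  metabolite emits several strongly correlated bins, a large set of bins
  remains unannotated, batches shift intensities additively on the log
  scale, every sample carries a multiplicative dilution factor, and a few
  cells are nonpositive (a known artifact of spectral binning);
* a handful of metabolites whose log-abundance genuinely differs between
  LNSP and the pooled adverse outcomes (CAO).

This module generates cohorts and matrices with exactly that structure so
every later stage is testable without any data download.  Hormone
generators are log-normal with parameters solved analytically from the
published per-group median and IQR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES",
    "SimConfig",
    "SampleRecord",
    "lognormal_from_median_iqr",
    "generate_cohort",
    "generate_spectra",
    "cohort_to_frame",
    "write_outputs",
]

#: Final-outcome labels, LNSP first (the positive class downstream).
OUTCOMES = ("LNSP", "MISCARRIAGE", "PUL", "TEP")

# Per-group (median, IQR) of the plasma hormones, in U/L and nmol/L.
_BHCG = {"LNSP": (9893.0, 42310.0), "MISCARRIAGE": (607.0, 3562.0),
         "PUL": (100.0, 378.0), "TEP": (859.0, 2686.0)}
_PROG = {"LNSP": (57.0, 44.0), "MISCARRIAGE": (25.0, 44.0),
         "PUL": (12.0, 43.0), "TEP": (25.0, 42.0)}
# Demographics: age and BMI as (median, IQR); categoricals as proportions.
_AGE = {"LNSP": (30.0, 8.0), "MISCARRIAGE": (31.0, 10.0),
        "PUL": (31.0, 10.0), "TEP": (29.0, 10.0)}
_BMI = {"LNSP": (25.8, 7.9), "MISCARRIAGE": (25.8, 9.4),
        "PUL": (23.6, 6.3), "TEP": (24.7, 8.4)}
_CAUCASIAN = {"LNSP": 0.870, "MISCARRIAGE": 0.819, "PUL": 0.878, "TEP": 0.891}
_SMOKER = {"LNSP": 0.247, "MISCARRIAGE": 0.234, "PUL": 0.171, "TEP": 0.275}
_NULLIPARA = {"LNSP": 0.370, "MISCARRIAGE": 0.325, "PUL": 0.439, "TEP": 0.294}

# Serum metabolites commonly annotated in CPMG 1H spectra, with MSI
# assignment level and HMDB accession where one exists.
METABOLITES: List[Tuple[str, int, Optional[str]]] = [
    ("2-hydroxybutyrate", 2, "HMDB0000008"),
    ("2-hydroxyisovalerate", 2, "HMDB0000407"),
    ("2-hydroxyvalerate", 2, "HMDB0001863"),
    ("3-hydroxybutyrate", 2, "HMDB0000357"),
    ("acetate", 1, "HMDB0000042"),
    ("citrate", 1, "HMDB0000094"),
    ("creatine", 1, "HMDB0000064"),
    ("creatinine", 1, "HMDB0000562"),
    ("d-glucose", 1, "HMDB0000122"),
    ("formate", 2, "HMDB0304356"),
    ("lactate", 1, "HMDB0000190"),
    ("l-alanine", 1, "HMDB0000161"),
    ("l-arginine", 2, "HMDB0000517"),
    ("l-glutamate", 1, "HMDB0000148"),
    ("l-glutamine", 1, "HMDB0000641"),
    ("l-glycine", 2, "HMDB0000123"),
    ("l-histidine", 2, "HMDB0000177"),
    ("l-isoleucine", 1, "HMDB0000172"),
    ("l-leucine", 1, "HMDB0000687"),
    ("l-lysine", 1, "HMDB0000182"),
    ("l-phenylalanine", 1, "HMDB0000159"),
    ("l-proline", 2, "HMDB0000162"),
    ("l-threonine", 1, "HMDB0000167"),
    ("l-tyrosine", 1, "HMDB0000158"),
    ("l-valine", 1, "HMDB0000883"),
    ("lipid", 3, None),
    ("mobile-lipids", 3, None),
    ("mobile-lipids-hdl", 3, None),
    ("mobile-lipids-ldl", 3, None),
    ("mobile-lipids-vldl", 3, None),
    ("myo-inositol", 1, "HMDB0000211"),
    ("unresolved-ch2", 3, None),
]

# Planted LNSP-vs-CAO effects (standardized log2 difference, LNSP minus
# CAO, per bin): amino acids that rise in viable early gestation carry
# positive signs, those consumed by the conceptus negative ones.
DEFAULT_PLANTED: Dict[str, float] = {
    "acetate": -0.50,
    "l-alanine": -0.40,
    "l-arginine": -0.35,
    "l-glutamate": 0.60,
    "l-glutamine": -0.45,
    "l-phenylalanine": 0.55,
    "citrate": 0.30,
    "lactate": 0.70,
    "l-glycine": -0.80,
}

_Z75 = 0.6744897501960817  # standard normal upper quartile


def lognormal_from_median_iqr(median: float, iqr: float) -> Tuple[float, float]:
    """Solve (mu, sigma) of a log-normal from its median and IQR.

    For X = exp(mu + sigma Z), median = exp(mu) and
    IQR = exp(mu) * 2 sinh(sigma * z75), hence
    sigma = asinh(IQR / (2 median)) / z75.
    """
    if median <= 0 or iqr <= 0:
        raise ValueError("median and IQR must be positive")
    mu = math.log(median)
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75
    return mu, sigma


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the cohort/spectra generator.

    Defaults reproduce the study conditions: group sizes 146/77/42/51,
    hormone log-normals calibrated to the published per-group median and
    IQR, 32 metabolites emitting 3 bins each plus 70 unannotated bins,
    nine planted discriminative metabolites.
    """

    group_sizes: Dict[str, int] = field(default_factory=lambda: {
        "LNSP": 146, "MISCARRIAGE": 77, "PUL": 42, "TEP": 51})
    n_metabolites: int = 32
    bins_per_metabolite: int = 3
    n_unannotated: int = 70
    planted_signals: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED))
    #: shared-signal fraction between sibling bins; a single float applies
    #: to every metabolite, a sequence gives one value per metabolite
    #: (bins in overlapped spectral regions integrate less cleanly)
    within_metabolite_rho: float | Tuple[float, ...] = 0.9
    n_batches: int = 3
    batch_effect_sd: float = 0.3     # additive per-bin shift, log2 units
    dilution_sd: float = 0.15        # per-sample log-scale spread
    nonpositive_rate: float = 0.01   # fraction of cells forced <= 0
    fwhm_mean: float = 1.1           # Hz, alignment-peak linewidth
    fwhm_sd: float = 0.08
    fwhm_outlier_rate: float = 0.03  # broad-line spectra the QC stage must catch
    fwhm_outlier_shift: float = 0.8  # Hz added to contaminated spectra
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be nonnegative")
        if set(self.group_sizes) - set(OUTCOMES):
            raise ValueError(f"unknown outcome in group_sizes: "
                             f"{set(self.group_sizes) - set(OUTCOMES)}")
        if sum(self.group_sizes.values()) == 0:
            raise ValueError("empty cohort: all group sizes are zero")
        rhos = self.rho_per_metabolite()
        if len(rhos) != self.n_metabolites:
            raise ValueError("within_metabolite_rho sequence must have one "
                             "value per metabolite")
        if not all(0.0 < r < 1.0 for r in rhos):
            raise ValueError("within_metabolite_rho must be in (0, 1)")
        if self.n_metabolites < 0 or self.n_unannotated < 0:
            raise ValueError("counts must be nonnegative")
        if self.bins_per_metabolite < 1:
            raise ValueError("bins_per_metabolite must be >= 1")
        if not all(math.isfinite(d) for d in self.planted_signals.values()):
            raise ValueError("planted effect sizes must be finite")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if not (0.0 <= self.nonpositive_rate < 1.0):
            raise ValueError("nonpositive_rate must be in [0, 1)")

    def rho_per_metabolite(self) -> List[float]:
        if isinstance(self.within_metabolite_rho, (int, float)):
            return [float(self.within_metabolite_rho)] * self.n_metabolites
        return [float(r) for r in self.within_metabolite_rho]

    def metabolite_names(self) -> List[str]:
        names = [m[0] for m in METABOLITES[: self.n_metabolites]]
        while len(names) < self.n_metabolites:
            names.append(f"metabolite-{len(names) + 1:02d}")
        return names

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SampleRecord:
    """One participant: outcome, demographics, hormones, acquisition QC."""

    sample_id: str
    outcome: str                 # LNSP | MISCARRIAGE | PUL | TEP
    binary_label: str            # LNSP | CAO
    age: float                   # years
    bmi: float                   # kg/m^2
    gestational_age: int         # completed weeks, <= 10 (inclusion criterion)
    bhcg: float                  # U/L
    progesterone: float          # nmol/L
    smoker: bool
    nullipara: bool
    ethnicity: str               # Caucasian | Other
    batch: str                   # acquisition batch label
    fwhm: float                  # Hz, alignment-peak full width half maximum


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent streams for cohort and spectra so one can be regenerated
    # without disturbing the other
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def generate_cohort(config: SimConfig) -> List[SampleRecord]:
    """Draw a cohort of :class:`SampleRecord` with the configured group sizes.

    Hormones are log-normal per group, calibrated so the population median
    and IQR match the configured targets.  Age is truncated normal
    (>= 18 years, the inclusion criterion), BMI log-normal, gestational
    age discrete uniform on 4..10 weeks.
    """
    config.validate()
    rng = _rng(config, 0)
    records: List[SampleRecord] = []
    idx = 0
    for outcome in OUTCOMES:
        n = int(config.group_sizes.get(outcome, 0))
        if n == 0:
            continue
        mu_h, sd_h = lognormal_from_median_iqr(*_BHCG[outcome])
        mu_p, sd_p = lognormal_from_median_iqr(*_PROG[outcome])
        mu_b, sd_b = lognormal_from_median_iqr(*_BMI[outcome])
        bhcg = np.exp(rng.normal(mu_h, sd_h, n))
        prog = np.exp(rng.normal(mu_p, sd_p, n))
        med_a, iqr_a = _AGE[outcome]
        age = np.clip(np.round(rng.normal(med_a, iqr_a / (2 * _Z75), n)), 18, 45)
        bmi = np.clip(np.exp(rng.normal(mu_b, sd_b, n)), 15.0, 55.0)
        ga = rng.integers(4, 11, n)
        smoker = rng.random(n) < _SMOKER[outcome]
        nullip = rng.random(n) < _NULLIPARA[outcome]
        cauc = rng.random(n) < _CAUCASIAN[outcome]
        batch = rng.integers(0, config.n_batches, n)
        fwhm = rng.normal(config.fwhm_mean, config.fwhm_sd, n)
        outlier = rng.random(n) < config.fwhm_outlier_rate
        fwhm = np.where(
            outlier, fwhm + config.fwhm_outlier_shift + rng.normal(0, 0.2, n), fwhm)
        for i in range(n):
            records.append(SampleRecord(
                sample_id=f"S{idx:04d}",
                outcome=outcome,
                binary_label="LNSP" if outcome == "LNSP" else "CAO",
                age=float(age[i]),
                bmi=float(round(bmi[i], 1)),
                gestational_age=int(ga[i]),
                bhcg=float(round(bhcg[i], 1)),
                progesterone=float(round(prog[i], 1)),
                smoker=bool(smoker[i]),
                nullipara=bool(nullip[i]),
                ethnicity="Caucasian" if cauc[i] else "Other",
                batch=f"B{int(batch[i]) + 1}",
                fwhm=float(round(fwhm[i], 3)),
            ))
            idx += 1
    return records


def cohort_to_frame(cohort: List[SampleRecord]) -> pd.DataFrame:
    """Tabulate a cohort, indexed by sample id."""
    df = pd.DataFrame([vars(r) for r in cohort]).set_index("sample_id")
    return df


def _ppm_labels(n_bins: int, rng: np.random.Generator) -> List[str]:
    # descending ppm axis, variable bin widths with small gaps, as produced
    # by intelligent binning of a 1D spectrum
    widths = rng.uniform(0.010, 0.050, n_bins)
    gaps = rng.uniform(0.004, 0.020, n_bins)
    hi = 9.5
    labels = []
    for w, g in zip(widths, gaps):
        lo = hi - w
        labels.append(f"{hi:.3f}–{lo:.3f}")
        hi = lo - g
    return labels


def generate_spectra(
    cohort: List[SampleRecord], config: SimConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a binned intensity matrix and its annotation map.

    Returns ``(matrix, annotation)``: the matrix is samples x bins with
    ppm-range column labels; the annotation maps annotated bin ids to
    ``(metabolite, msi_level, hmdb_id)`` and omits unannotated bins.

    Construction, per bin on the log2 scale: a shared per-metabolite latent
    (inducing pairwise correlation ``within_metabolite_rho`` between sibling
    bins), a planted standardized LNSP-vs-CAO shift applied to every bin of
    a planted metabolite, an additive per-batch per-bin effect, a per-bin
    baseline and scale, and a per-sample dilution offset.  Intensities are
    exponentiated back; a random subset of cells then has a baseline offset
    subtracted to force occasional nonpositive values.
    """
    config.validate()
    if not cohort:
        raise ValueError("cohort must be nonempty")
    valid_batches = {f"B{i + 1}" for i in range(config.n_batches)}
    bad = {r.batch for r in cohort} - valid_batches
    if bad:
        raise ValueError(
            f"cohort batch labels {sorted(bad)} not generated by a "
            f"{config.n_batches}-batch configuration")

    rng = _rng(config, 1)
    n = len(cohort)
    names = config.metabolite_names()
    unknown = set(config.planted_signals) - set(names)
    if unknown:
        raise ValueError(f"planted_signals reference unknown metabolites: "
                         f"{sorted(unknown)}")
    n_bins = config.n_metabolites * config.bins_per_metabolite + config.n_unannotated
    bin_labels = _ppm_labels(n_bins, rng)
    # scatter metabolite bins across the ppm axis like a real spectrum
    owner = ([m for m in range(config.n_metabolites)
              for _ in range(config.bins_per_metabolite)]
             + [-1] * config.n_unannotated)
    owner = np.array(owner)
    rng.shuffle(owner)

    is_lnsp = np.array([r.binary_label == "LNSP" for r in cohort], dtype=float)
    batch_idx = np.array([int(r.batch[1:]) - 1 for r in cohort])

    rhos = config.rho_per_metabolite()
    latent = rng.normal(size=(n, config.n_metabolites))
    log2m = np.empty((n, n_bins))
    info = {name: i for i, name in enumerate(names)}
    effects = np.zeros(config.n_metabolites)
    for name, d in config.planted_signals.items():
        effects[info[name]] = d
    baseline = rng.uniform(12.0, 20.0, n_bins)
    scale = rng.uniform(0.5, 1.5, n_bins)
    batch_fx = rng.normal(0.0, config.batch_effect_sd,
                          size=(config.n_batches, n_bins))
    dilution = rng.normal(0.0, config.dilution_sd, n) / math.log(2)

    for j in range(n_bins):
        m = owner[j]
        if m >= 0:
            z = (math.sqrt(rhos[m]) * latent[:, m]
                 + math.sqrt(1.0 - rhos[m]) * rng.normal(size=n)
                 + effects[m] * is_lnsp)
        else:
            z = rng.normal(size=n)
        log2m[:, j] = baseline[j] + scale[j] * z
    log2m += batch_fx[batch_idx, :]
    log2m += dilution[:, None]
    values = np.exp2(log2m)

    if config.nonpositive_rate > 0:
        mask = rng.random(values.shape) < config.nonpositive_rate
        # keep at least one positive cell per bin (a bin with no positive
        # value cannot be imputed downstream)
        full = mask.all(axis=0)
        mask[0, full] = False
        u = rng.uniform(0.0, 0.5, values.shape)
        # subtract a baseline offset slightly exceeding the cell value
        values = np.where(mask, -u * 0.05 * values, values)

    sample_ids = [r.sample_id for r in cohort]
    matrix = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                          columns=bin_labels)
    meta = {m[0]: m for m in METABOLITES}
    ann_rows = []
    for j in range(n_bins):
        m = owner[j]
        if m < 0:
            continue
        name = names[m]
        msi, hmdb = (meta[name][1], meta[name][2]) if name in meta else (3, None)
        ann_rows.append({"bin_id": bin_labels[j], "metabolite": name,
                         "msi_level": msi, "hmdb_id": hmdb})
    annotation = pd.DataFrame(
        ann_rows, columns=["bin_id", "metabolite", "msi_level", "hmdb_id"]
    ).set_index("bin_id")
    return matrix, annotation


def write_outputs(outdir: str | Path, cohort: List[SampleRecord],
                  matrix: pd.DataFrame, annotation: pd.DataFrame) -> Dict[str, Path]:
    """Write cohort CSV, feature-matrix TSV and annotation TSV to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "matrix": outdir / "matrix.tsv",
        "annotation": outdir / "annotation.tsv",
    }
    cohort_to_frame(cohort).to_csv(paths["cohort"])
    matrix.to_csv(paths["matrix"], sep="\t")
    annotation.to_csv(paths["annotation"], sep="\t")
    return paths
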