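"""Refinement of a raw bin-intensity table into the analysis matrix.

The fixed stage order is::

    qc_filter_fwhm -> replace_nonpositive -> crs_reduce -> pqn_log2 -> batch_correct

* **QC filter** — spectra whose alignment-peak FWHM exceeds the cohort
  mean by more than ``k`` standard deviations are excluded (broad lines
  violate minimum reporting standards; narrow lines do not, so the filter
  is one-sided).
* **Nonpositive replacement** — binning produces occasional nonpositive
  intensities; each is replaced by one fifth of the smallest positive
  value of its bin.
* **CRS reduction** — a metabolite emitting several bins is redundant.
  Each bin is scored by its mean Pearson correlation with its sibling
  bins (the correlation reliability score, CRS); the best-scoring bin
  represents the metabolite when that score reaches a global passing
  threshold (median minus SD of the per-metabolite best scores), else all
  of the metabolite's bins are kept at lower annotation confidence.
  Unannotated bins are always kept.
* **PQN** — probabilistic quotient normalization against the per-bin
  median reference removes per-sample dilution; intensities are then
  log2 transformed.
* **Batch correction** — per-bin per-batch location/scale effects are
  estimated on standardized data, shrunk toward their across-bin moments
  by parametric empirical Bayes, and removed; grand means and preserved
  covariate effects are restored.

A :class:`Preprocessor` wraps the stages in fit/transform form so that
every parameter (QC threshold, per-bin minimum positives, kept bins, PQN
reference, batch adjustments) can be estimated on a discovery set and
applied frozen to held-out samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CRSResult",
    "NormalizationResult",
    "BatchModel",
    "Preprocessor",
    "qc_filter_fwhm",
    "replace_nonpositive",
    "crs_reduce",
    "pqn_log2",
    "batch_correct",
    "annotation_rate",
]


def qc_filter_fwhm(fwhm: pd.Series, k: float = 2.0) -> List[str]:
    """Sample ids whose FWHM is within ``mean + k * SD`` (order preserved).

    One-sided: only broad alignment peaks are excluded.  With zero
    variance every sample is kept.
    """
    x = pd.Series(fwhm).astype(float)
    finite = x[np.isfinite(x)]
    if len(finite) < 2:
        raise ValueError("need at least two samples with finite FWHM")
    thr = float(finite.mean() + k * finite.std(ddof=1))
    kept = x.index[(x <= thr) & np.isfinite(x)]
    return list(kept)


def replace_nonpositive(matrix: pd.DataFrame, factor: float = 0.2) -> pd.DataFrame:
    """Replace each nonpositive cell by ``factor`` x the bin's minimum positive.

    Positive cells are untouched.  A bin with no positive value cannot be
    imputed and raises ``ValueError`` naming the bin.
    """
    values = matrix.to_numpy(dtype=float, copy=True)
    pos = np.where(values > 0, values, np.inf)
    min_pos = pos.min(axis=0)
    dead = ~np.isfinite(min_pos)
    if dead.any():
        bad = list(matrix.columns[dead])
        raise ValueError(f"bins with no positive value: {bad}")
    repl = factor * min_pos
    values = np.where(values > 0, values, repl[None, :])
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


@dataclass
class CRSResult:
    """Per-metabolite correlation reliability scores and the reduction verdict."""

    scores: Dict[str, List[Tuple[str, float]]]      # metabolite -> [(bin, CRS)]
    representative: Dict[str, str]                   # metabolite -> best bin
    passed: Dict[str, bool]                          # best CRS >= passing score
    passing_score: float                             # median - SD of best scores
    kept_bins: List[str] = field(default_factory=list)


def crs_scores(matrix: pd.DataFrame, bins: Sequence[str],
               method: str = "pearson") -> List[Tuple[str, float]]:
    """CRS of each bin: mean correlation with its sibling bins."""
    if len(bins) == 1:
        return [(bins[0], 1.0)]  # nothing to corroborate against, by convention
    sub = matrix.loc[:, list(bins)]
    corr = sub.corr(method=method).to_numpy()
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(corr, axis=1)
    return list(zip(bins, mean_corr.tolist()))


def crs_reduce(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str = "pearson",
    passing_score: Optional[float] = None,
    log_scale: bool = True,
) -> Tuple[pd.DataFrame, CRSResult]:
    """Collapse redundant bins of each metabolite to one representative.

    ``annotation`` is indexed by bin id with a ``metabolite`` column.  The
    global passing threshold defaults to ``median - SD`` of the best CRS
    over multi-bin metabolites; pass ``passing_score`` to freeze it (e.g.
    when applying a discovery-estimated reduction to new samples).
    Scores are computed on log2 intensities by default (bin intensities
    are log-normal, so their association is linear on the log scale;
    raw-scale Pearson is attenuated by skew in proportion to each bin's
    dynamic range).  Column order of the input is preserved among kept
    bins; the returned matrix stays on the original scale.
    """
    missing = [b for b in annotation.index if b not in matrix.columns]
    if missing:
        raise ValueError(f"annotation references bins absent from the "
                         f"matrix: {missing[:5]}")
    groups: Dict[str, List[str]] = {}
    for bin_id, row in annotation.iterrows():
        groups.setdefault(str(row["metabolite"]), []).append(str(bin_id))

    score_matrix = matrix
    if log_scale:
        if not (matrix.to_numpy() > 0).all():
            raise ValueError("nonpositive values; apply replace_nonpositive "
                             "before crs_reduce")
        score_matrix = np.log2(matrix)

    scores: Dict[str, List[Tuple[str, float]]] = {}
    representative: Dict[str, str] = {}
    best: Dict[str, float] = {}
    for met, bins in groups.items():
        sc = crs_scores(score_matrix, bins, method=method)
        scores[met] = sc
        rep, b = max(sc, key=lambda t: (t[1], t[0]))
        representative[met] = rep
        best[met] = b

    multi_best = np.array([best[m] for m, b in groups.items() if len(b) > 1])
    if passing_score is None:
        if multi_best.size == 0:
            passing_score = -1.0  # no redundancy anywhere: everything passes
        else:
            sd = float(np.std(multi_best, ddof=1)) if multi_best.size > 1 else 0.0
            passing_score = float(np.median(multi_best) - sd)

    passed = {m: (len(groups[m]) == 1 or best[m] >= passing_score)
              for m in groups}
    drop = set()
    for met, bins in groups.items():
        if len(bins) > 1 and passed[met]:
            drop.update(b for b in bins if b != representative[met])
    kept = [c for c in matrix.columns if c not in drop]
    result = CRSResult(scores=scores, representative=representative,
                       passed=passed, passing_score=float(passing_score),
                       kept_bins=kept)
    return matrix.loc[:, kept], result


@dataclass
class NormalizationResult:
    """PQN output: normalized log2 matrix, dilution factors, reference."""

    matrix: pd.DataFrame
    dilution_factor: pd.Series
    reference_spectrum: pd.Series


def pqn_log2(matrix: pd.DataFrame,
             reference: Optional[pd.Series] = None) -> NormalizationResult:
    """Probabilistic quotient normalization followed by log2.

    The per-sample dilution factor is the median over bins of the
    quotient against the reference spectrum (per-bin median across
    samples unless a frozen reference is supplied); each sample is
    divided by its factor before the log2 transform.
    """
    values = matrix.to_numpy(dtype=float)
    if not (values > 0).all():
        raise ValueError("matrix contains nonpositive values; apply "
                         "replace_nonpositive first")
    if reference is None:
        reference = matrix.median(axis=0)
    ref = reference.reindex(matrix.columns).to_numpy(dtype=float)
    if not (ref > 0).all():
        raise ValueError("reference spectrum must be strictly positive")
    factors = np.median(values / ref[None, :], axis=1)
    normalized = np.log2(values / factors[:, None])
    return NormalizationResult(
        matrix=pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns),
        dilution_factor=pd.Series(factors, index=matrix.index, name="dilution_factor"),
        reference_spectrum=pd.Series(ref, index=matrix.columns, name="reference"),
    )


@dataclass
class BatchModel:
    """Frozen batch-adjustment parameters for out-of-sample application."""

    batches: List[str]
    grand_mean: np.ndarray        # per bin
    pooled_sd: np.ndarray         # per bin
    gamma: Dict[str, np.ndarray]  # per batch: per-bin location effect
    delta: Dict[str, np.ndarray]  # per batch: per-bin scale effect (SD units)
    columns: List[str] = field(default_factory=list)

    def transform(self, matrix: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
        """Apply the stored adjustments to new samples by batch label."""
        y = matrix.loc[:, self.columns].to_numpy(dtype=float, copy=True)
        labels = batch.reindex(matrix.index)
        unknown = set(labels) - set(self.batches)
        if unknown:
            raise ValueError(f"unseen batch labels: {sorted(unknown)}")
        z = (y - self.grand_mean[None, :]) / self.pooled_sd[None, :]
        for b in self.batches:
            rows = (labels == b).to_numpy()
            if not rows.any():
                continue
            z[rows] = (z[rows] - self.gamma[b][None, :]) / self.delta[b][None, :]
        adj = z * self.pooled_sd[None, :] + self.grand_mean[None, :]
        return pd.DataFrame(adj, index=matrix.index, columns=self.columns)


def _eb_shrink(z: np.ndarray, n_iter: int = 200,
               tol: float = 1e-5) -> Tuple[np.ndarray, np.ndarray]:
    """Parametric empirical-Bayes batch location/scale for one batch.

    ``z`` is the standardized data restricted to the batch (n_i x p).
    Location effects shrink toward a normal prior, variance effects toward
    an inverse-gamma prior, both moment-matched across bins; the joint
    solution is found by the standard fixed-point iteration.
    """
    n_i = z.shape[0]
    g_hat = z.mean(axis=0)
    d_hat = z.var(axis=0, ddof=1)
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1)
    m, v = d_hat.mean(), d_hat.var(ddof=1)
    if v <= 0:
        return g_hat, d_hat
    a_prior = (2 * v + m ** 2) / v
    b_prior = (m * v + m ** 3) / v
    g_star, d_star = g_hat.copy(), d_hat.copy()
    for _ in range(n_iter):
        g_new = (n_i * t2 * g_hat + d_star * g_bar) / (n_i * t2 + d_star)
        sse = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sse + b_prior) / (n_i / 2.0 + a_prior - 1.0)
        change = max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max())
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def batch_correct(
    matrix: pd.DataFrame,
    batch: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    method: str = "eb",
) -> Tuple[pd.DataFrame, BatchModel]:
    """Remove per-bin per-batch location/scale effects from log-scale data.

    ``method="eb"`` shrinks the per-batch estimates toward their
    across-bin moments (parametric empirical Bayes); ``"standardize"``
    uses the raw estimates, which on covariate-free data reduces to
    per-bin per-batch standardization to the pooled mean and variance;
    ``"none"`` is a pass-through.  ``covariates`` (e.g. the outcome label,
    dummy-coded) are retained in the output.
    """
    if method not in {"eb", "standardize", "none"}:
        raise ValueError(f"unknown batch method: {method!r}")
    batch = batch.reindex(matrix.index)
    levels = [str(b) for b in pd.unique(batch)]
    y = matrix.to_numpy(dtype=float)
    n, p = y.shape

    if method == "none" or len(levels) == 1:
        model = BatchModel(batches=levels, grand_mean=y.mean(axis=0),
                           pooled_sd=np.ones(p),
                           gamma={b: np.zeros(p) for b in levels},
                           delta={b: np.ones(p) for b in levels},
                           columns=list(matrix.columns))
        return matrix.copy(), model

    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batch scale inestimable for single-sample "
                         f"batches: {list(small.index)}")

    onehot = pd.get_dummies(batch.astype(str), dtype=float)[levels].to_numpy()
    design = [onehot]
    if covariates is not None:
        cov = pd.get_dummies(covariates.reindex(matrix.index), drop_first=True)
        design.append(cov.to_numpy(dtype=float))
    X = np.hstack(design)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    nb = len(levels)
    weights = np.array([counts[b] for b in levels], dtype=float) / n
    grand = weights @ beta[:nb]                       # per-bin weighted grand mean
    cov_part = X[:, nb:] @ beta[nb:] if X.shape[1] > nb else np.zeros_like(y)
    resid = y - X @ beta
    sigma2 = (resid ** 2).mean(axis=0)
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))
    stand_mean = grand[None, :] + cov_part
    z = (y - stand_mean) / sigma[None, :]

    gamma: Dict[str, np.ndarray] = {}
    delta: Dict[str, np.ndarray] = {}
    z_adj = np.empty_like(z)
    for b in levels:
        rows = (batch == b).to_numpy()
        zb = z[rows]
        if method == "eb":
            g, d2 = _eb_shrink(zb)
        else:
            g, d2 = zb.mean(axis=0), zb.var(axis=0, ddof=1)
        d = np.sqrt(np.maximum(d2, 1e-12))
        gamma[b], delta[b] = g, d
        z_adj[rows] = (zb - g[None, :]) / d[None, :]

    adjusted = z_adj * sigma[None, :] + stand_mean
    out = pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)
    model = BatchModel(batches=levels, grand_mean=grand, pooled_sd=sigma,
                       gamma=gamma, delta=delta, columns=list(matrix.columns))
    return out, model


def annotation_rate(n_annotated: int, n_total: int) -> float:
    """Annotated-bin percentage, rounded to one decimal (92 of 162 -> 56.8)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_annotated / n_total, 1)


class Preprocessor:
    """Fit the full preprocessing chain on one set, apply it frozen to another.

    ``fit`` estimates the QC threshold, per-bin minimum positives, CRS
    reduction, PQN reference and batch adjustments on the supplied
    (discovery) samples and stores the processed matrix as ``matrix_``;
    ``transform`` applies all parameters unchanged to held-out samples,
    which is the strict no-leakage mode of the pipeline.
    """

    def __init__(self, k_sd: Optional[float] = 2.0, replace_factor: float = 0.2,
                 crs_method: str = "pearson", batch_method: str = "eb"):
        # k_sd=None skips the QC stage (e.g. when the filter already ran
        # upstream of the discovery/validation split)
        self.k_sd = k_sd
        self.replace_factor = replace_factor
        self.crs_method = crs_method
        self.batch_method = batch_method
        self.log_: List[Tuple[str, int, int]] = []  # (stage, n samples, n bins)

    def fit(self, matrix: pd.DataFrame, annotation: pd.DataFrame,
            fwhm: pd.Series, batch: pd.Series,
            covariates: Optional[pd.DataFrame] = None) -> "Preprocessor":
        self.log_ = [("input", *matrix.shape)]
        finite = fwhm.reindex(matrix.index).astype(float)
        if self.k_sd is None:
            self.fwhm_threshold_ = float("inf")
        else:
            self.fwhm_threshold_ = float(
                finite.mean() + self.k_sd * finite.std(ddof=1))
        kept = [s for s in matrix.index if finite[s] <= self.fwhm_threshold_]
        m = matrix.loc[kept]
        self.log_.append(("qc_filter", *m.shape))

        pos = m.to_numpy(dtype=float)
        pos = np.where(pos > 0, pos, np.inf).min(axis=0)
        if not np.isfinite(pos).all():
            bad = list(m.columns[~np.isfinite(pos)])
            raise ValueError(f"bins with no positive value: {bad}")
        self.min_positive_ = pd.Series(pos, index=m.columns)
        m = self._replace(m)
        self.log_.append(("replace_nonpositive", *m.shape))

        m, self.crs_ = crs_reduce(m, annotation, method=self.crs_method)
        self.log_.append(("crs_reduce", *m.shape))

        norm = pqn_log2(m)
        self.pqn_reference_ = norm.reference_spectrum
        self.dilution_factor_ = norm.dilution_factor
        m = norm.matrix
        self.log_.append(("pqn_log2", *m.shape))

        m, self.batch_model_ = batch_correct(
            m, batch.reindex(m.index), covariates=covariates,
            method=self.batch_method)
        self.log_.append(("batch_correct", *m.shape))
        self.matrix_ = m
        return self

    def _replace(self, matrix: pd.DataFrame) -> pd.DataFrame:
        repl = self.replace_factor * self.min_positive_.reindex(matrix.columns)
        values = matrix.to_numpy(dtype=float, copy=True)
        values = np.where(values > 0, values, repl.to_numpy()[None, :])
        return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)

    def transform(self, matrix: pd.DataFrame, fwhm: pd.Series,
                  batch: pd.Series) -> pd.DataFrame:
        finite = fwhm.reindex(matrix.index).astype(float)
        kept = [s for s in matrix.index if finite[s] <= self.fwhm_threshold_]
        if len(kept) < len(matrix):
            warnings.warn(f"QC filter excluded {len(matrix) - len(kept)} "
                          f"held-out samples")
        m = self._replace(matrix.loc[kept])
        m = m.loc[:, self.crs_.kept_bins]
        norm = pqn_log2(m, reference=self.pqn_reference_)
        return self.batch_model_.transform(norm.matrix, batch)
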