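"""Cohort description and covariate-adjusted differential abundance.

Continuous demographics and hormones are summarized as median (IQR) per
outcome group and compared by Kruskal–Wallis (with Dunn's rank-based
post-hoc available); categoricals as n (%) with a chi-squared test.

Differential abundance between LNSP and CAO fits one fixed-effect linear
model per bin, ``intensity ~ group + age + BMI + gestational age``, then
moderates the per-bin residual variances by empirical Bayes: the
variances are assumed to follow a scaled inverse-chi-square prior whose
hyperparameters (prior_df d0, prior_variance s0^2) are moment-matched on
the log residual variances; the posterior variances

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

yield moderated t statistics on d0 + df degrees of freedom.  Multiplicity
is controlled by Benjamini–Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "DEResult",
    "bh_adjust",
    "cohort_table",
    "dunn_posthoc",
    "spearman_screen",
    "fit_moderated",
    "covariate_variance_screen",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    NaN entries are excluded from the ranking and propagate as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    q[ok] = out
    return q


_CONTINUOUS = ["age", "bmi", "gestational_age", "bhcg", "progesterone"]
_CATEGORICAL = ["ethnicity", "smoker", "nullipara"]


def cohort_table(
    cohort: pd.DataFrame,
    group_col: str = "outcome",
    continuous: Sequence[str] = tuple(_CONTINUOUS),
    categorical: Sequence[str] = tuple(_CATEGORICAL),
    yates: bool = False,
) -> pd.DataFrame:
    """Demographics table: per-group summaries with an omnibus test per row.

    Continuous rows report ``median (IQR)`` and a Kruskal–Wallis p-value;
    categorical rows report ``n (%)`` of the modal (or True) level and a
    chi-squared p-value (no continuity correction unless ``yates``).
    Constant categoricals have an undefined test, reported as NaN.
    """
    groups = [g for g in cohort[group_col].unique()]
    if sum(cohort[group_col].value_counts() > 0) < 2:
        raise ValueError("need at least two nonempty groups")
    rows = []
    n_row: Dict[str, object] = {"variable": "n", "test": "", "statistic": np.nan,
                                "p": np.nan}
    for g in groups:
        n_row[g] = str((cohort[group_col] == g).sum())
    rows.append(n_row)

    for var in continuous:
        samples = [cohort.loc[cohort[group_col] == g, var].dropna().to_numpy()
                   for g in groups]
        row: Dict[str, object] = {"variable": var, "test": "kruskal-wallis"}
        for g, x in zip(groups, samples):
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            row[g] = f"{med:g} ({q3 - q1:g})"
        try:
            stat, p = sps.kruskal(*samples)
        except ValueError:  # all values identical across every group
            stat, p = 0.0, 1.0
        row["statistic"], row["p"] = float(stat), float(p)
        rows.append(row)

    for var in categorical:
        ct = pd.crosstab(cohort[var], cohort[group_col])
        row = {"variable": var, "test": "chi-squared"}
        levels = ct.index.tolist()
        top = True if True in levels else ct.sum(axis=1).idxmax()
        for g in groups:
            n_g = int((cohort[group_col] == g).sum())
            k = int(ct.loc[top, g]) if g in ct.columns else 0
            row[g] = f"{k} ({100.0 * k / n_g:.1f})" if n_g else "0 (0.0)"
        if len(levels) < 2:
            row["statistic"], row["p"] = np.nan, np.nan
            warnings.warn(f"categorical variable {var!r} is constant; "
                          f"chi-squared undefined")
        else:
            stat, p, *_ = sps.chi2_contingency(ct.to_numpy(), correction=yates)
            row["statistic"], row["p"] = float(stat), float(p)
        rows.append(row)
    cols = ["variable", *groups, "test", "statistic", "p"]
    return pd.DataFrame(rows)[cols]


def dunn_posthoc(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Dunn's rank-sum pairwise comparisons with BH-adjusted p-values."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ranks = sps.rankdata(v)
    n = v.size
    # tie correction term for the variance of mean-rank differences
    _, counts = np.unique(v, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    labels = pd.unique(g)
    mean_rank = {lab: ranks[g == lab].mean() for lab in labels}
    sizes = {lab: (g == lab).sum() for lab in labels}
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(tie * n * (n + 1) / 12.0
                         * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p": 2 * sps.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


_PAIRS = [("gestational_age", "bhcg"),
          ("gestational_age", "progesterone"),
          ("bhcg", "progesterone")]


def spearman_screen(cohort: pd.DataFrame,
                    group_col: str = "outcome") -> pd.DataFrame:
    """Spearman rho and p for hormone/gestation pairs within each group."""
    rows = []
    for g, sub in cohort.groupby(group_col, sort=False):
        for x, y in _PAIRS:
            xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
            if len(xv) < 3:
                raise ValueError(f"group {g!r} has fewer than 3 pairs")
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rows.append({"group": g, "x": x, "y": y, "rho": np.nan,
                             "p": np.nan, "note": "constant variable"})
                continue
            rho, p = sps.spearmanr(xv, yv)
            rows.append({"group": g, "x": x, "y": y, "rho": float(rho),
                         "p": float(p), "note": ""})
    return pd.DataFrame(rows)


def _trigamma_inverse(y: float, n_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(n_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> Tuple[float, float, np.ndarray]:
    """Moment-match a scaled inverse-chi-square prior on residual variances.

    Returns ``(prior_df, prior_var, posterior_var)``.  Hyperparameters are
    estimated from the mean and excess variance of log residual variances,
    using the exact moments of log chi-square.
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    if s2.size > 1:
        e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    else:
        e_var = 0.0
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0, s0 = np.inf, float(np.exp(e_mean))
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return float(d0), s0, post


@dataclass
class DEResult:
    """Per-feature moderated differential-abundance statistics."""

    table: pd.DataFrame        # effect, se, t, p, q, df_resid per feature
    prior_df: float
    prior_var: float

    @property
    def significant(self) -> List[str]:
        return list(self.table.index[self.table["q"] < 0.05])


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy(float))
    if rank < X.shape[1]:
        collinear = []
        cols: List[str] = []
        for c in X.columns:
            cols.append(c)
            if np.linalg.matrix_rank(X[cols].to_numpy(float)) < len(cols):
                collinear.append(c)
                cols.pop()
        raise ValueError(f"singular design; collinear columns: {collinear}")


def fit_moderated(
    matrix: pd.DataFrame,
    labels: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    positive: str = "LNSP",
    prior_df: Optional[float] = None,
) -> DEResult:
    """Covariate-adjusted LNSP-vs-CAO contrast with EB variance moderation.

    ``labels`` holds the binary outcome; the reported effect is the
    adjusted log2 difference ``positive`` minus the other class.
    ``prior_df`` overrides the estimated prior degrees of freedom (0
    recovers ordinary t statistics, ``inf`` full shrinkage to s0^2).
    """
    y = matrix.to_numpy(dtype=float)
    lab = labels.reindex(matrix.index)
    classes = pd.unique(lab)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got {list(classes)}")
    group = (lab == positive).astype(float)
    design = pd.DataFrame({"intercept": 1.0, "group": group}, index=matrix.index)
    if covariates is not None:
        cov = pd.get_dummies(covariates.reindex(matrix.index), drop_first=True)
        design = pd.concat([design, cov.astype(float)], axis=1)
    n, k = design.shape
    if n <= k:
        raise ValueError("more design columns than samples")
    _check_design(design)

    X = design.to_numpy(float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = n - k
    s2 = (resid ** 2).sum(axis=0) / df
    c_gg = xtx_inv[1, 1]
    effect = beta[1]
    se_ord = np.sqrt(c_gg * s2)

    if prior_df is None:
        d0, s0, s2_post = squeeze_var(s2, df)
    elif prior_df == 0:
        d0, s0, s2_post = 0.0, float(np.median(s2)), s2.copy()
    elif np.isinf(prior_df):
        _, s0, _ = squeeze_var(s2, df)
        d0, s2_post = np.inf, np.full_like(s2, s0)
    else:
        _, s0, _ = squeeze_var(s2, df)
        d0 = float(prior_df)
        s2_post = (d0 * s0 + df * s2) / (d0 + df)

    se_mod = np.sqrt(c_gg * s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se_mod
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"effect": effect, "se": se_ord, "se_moderated": se_mod, "t": t,
         "p": p, "q": q, "df_resid": float(df)},
        index=matrix.columns)
    return DEResult(table=table, prior_df=float(d0), prior_var=float(s0))


def covariate_variance_screen(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Variance explained per bin by each covariate alone.

    For every covariate, fits a single-covariate linear model to each bin
    (categoricals dummy-coded) and records the R^2.  Returns the per-bin
    R^2 table and a summary (median and upper quartile across bins) used
    to decide which covariates enter the adjusted models.
    """
    if covariates is None:
        covariates = [c for c in metadata.columns]
    y = matrix.to_numpy(dtype=float)
    yc = y - y.mean(axis=0)
    tss = (yc ** 2).sum(axis=0)
    r2 = {}
    for cov in covariates:
        col = metadata.reindex(matrix.index)[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            Xc = col.to_numpy(float)[:, None]
        else:
            Xc = pd.get_dummies(col, drop_first=True).to_numpy(float)
        if Xc.shape[1] == 0 or np.allclose(Xc.std(axis=0), 0):
            warnings.warn(f"covariate {cov!r} is constant; R^2 set to 0")
            r2[cov] = np.zeros(matrix.shape[1])
            continue
        Xc = np.hstack([np.ones((len(col), 1)), Xc])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        rss = ((y - Xc @ beta) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[cov] = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    per_bin = pd.DataFrame(r2, index=matrix.columns)
    summary = pd.DataFrame({
        "median_r2": per_bin.median(axis=0),
        "q3_r2": per_bin.quantile(0.75, axis=0),
    })
    return per_bin, summary
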