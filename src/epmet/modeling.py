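"""Classifier training and validation-set evaluation.

Models discriminate LNSP (positive class) from the pooled adverse
outcomes using configurable variable blocks — stability-selected
metabolite signals, plasma hormones (β-hCG, progesterone) and
demographics (age, gestational age, BMI).  The six standard block
combinations form the reporting battery.  Metrics come from the
confusion matrix at the model's default decision rule (majority vote for
the random forest), with an exact Clopper–Pearson binomial interval on
accuracy and a midrank Mann–Whitney AUROC on probability scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

__all__ = [
    "HORMONES",
    "DEMOGRAPHICS",
    "TABLE_BLOCKS",
    "ModelSpec",
    "ModelMetrics",
    "assemble_design",
    "train_model",
    "evaluate",
    "metrics_from_predictions",
    "clopper_pearson",
    "auroc",
    "pca_scores",
    "run_model_battery",
]

HORMONES = ("bhcg", "progesterone")
DEMOGRAPHICS = ("age", "gestational_age", "bmi")

#: The six reported variable-block combinations.
TABLE_BLOCKS: List[Tuple[str, ...]] = [
    ("metabolites",),
    ("hormones",),
    ("metabolites", "hormones"),
    ("hormones", "demographics"),
    ("metabolites", "hormones", "demographics"),
    ("demographics",),
]


@dataclass(frozen=True)
class ModelSpec:
    """Which variable blocks feed which model type."""

    blocks: Tuple[str, ...] = ("metabolites",)
    model_type: str = "random_forest"   # "random_forest" | "glm"
    n_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("at least one variable block is required")
        bad = set(self.blocks) - {"metabolites", "hormones", "demographics"}
        if bad:
            raise ValueError(f"unknown blocks: {sorted(bad)}")
        if self.model_type not in {"random_forest", "glm"}:
            raise ValueError("model_type must be 'random_forest' or 'glm'")

    @property
    def name(self) -> str:
        return "+".join(self.blocks)


def assemble_design(
    blocks: Sequence[str],
    metadata: pd.DataFrame,
    features: Optional[pd.DataFrame] = None,
    selected: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Column-bind the requested variable blocks into one design table."""
    parts = []
    for block in blocks:
        if block == "metabolites":
            if features is None:
                raise ValueError("metabolites block requested but no feature "
                                 "matrix supplied")
            cols = list(selected) if selected is not None else list(features.columns)
            missing = [c for c in cols if c not in features.columns]
            if missing:
                raise ValueError(f"missing metabolite features: {missing}")
            parts.append(features.loc[:, cols])
        else:
            names = HORMONES if block == "hormones" else DEMOGRAPHICS
            missing = [c for c in names if c not in metadata.columns]
            if missing:
                raise ValueError(f"missing {block} variables: {missing}")
            parts.append(metadata.loc[:, list(names)].astype(float))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        raise ValueError("design contains missing values")
    return X


def train_model(X: pd.DataFrame, y: pd.Series, spec: ModelSpec):
    """Fit the configured classifier; deterministic under ``spec.seed``."""
    spec.validate()
    if len(pd.unique(y)) != 2:
        raise ValueError("labels must be binary")
    if spec.model_type == "random_forest":
        model = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1)
    else:
        model = LogisticRegression(max_iter=2000, random_state=spec.seed)
    model.fit(X.to_numpy(float), np.asarray(y))
    return model


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact binomial interval for a proportion.

    Interior cases use the alpha/2 beta-quantile identity; at the
    boundaries (k = 0 or k = n) the interval is one-sided at full alpha,
    so a perfect score on n trials has lower bound ``alpha ** (1/n)``.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    if k == 0:
        return 0.0, float(1.0 - alpha ** (1.0 / n))
    if k == n:
        return float(alpha ** (1.0 / n)), 1.0
    low = float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve via the midrank Mann–Whitney statistic."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ModelMetrics:
    """Confusion-matrix performance of one model on one evaluation set."""

    accuracy: float
    ci95_low: float
    ci95_high: float
    sensitivity: float
    specificity: float
    ppv: float
    f1: float
    auroc: float
    tp: int
    fn: int
    fp: int
    tn: int

    def as_row(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy, "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "f1": self.f1,
            "auroc": self.auroc, "tp": self.tp, "fn": self.fn,
            "fp": self.fp, "tn": self.tn,
        }


def metrics_from_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    scores: Optional[Sequence[float]] = None,
    positive: str = "LNSP",
) -> ModelMetrics:
    """Confusion-matrix metrics with the positive class LNSP.

    Sensitivity or specificity is NaN (with a warning) when the
    evaluation set lacks the corresponding class.
    """
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    tp = int((t & p).sum())
    fn = int((t & ~p).sum())
    fp = int((~t & p).sum())
    tn = int((~t & ~p).sum())
    n = tp + fn + fp + tn
    correct = tp + tn
    acc = correct / n
    low, high = clopper_pearson(correct, n)
    if tp + fn == 0:
        warnings.warn("no positive samples in evaluation set; "
                      "sensitivity undefined")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples in evaluation set; "
                      "specificity undefined")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    f1 = (2 * ppv * sens / (ppv + sens)
          if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
          else float("nan"))
    auc = float("nan")
    if scores is not None and 0 < t.sum() < n:
        auc = auroc(scores, t)
    return ModelMetrics(accuracy=acc, ci95_low=low, ci95_high=high,
                        sensitivity=sens, specificity=spec, ppv=ppv, f1=f1,
                        auroc=auc, tp=tp, fn=fn, fp=fp, tn=tn)


def evaluate(model, X: pd.DataFrame, y: pd.Series,
             positive: str = "LNSP") -> ModelMetrics:
    """Evaluate a fitted model on held-out samples at its default rule."""
    pred = model.predict(X.to_numpy(float))
    scores = None
    if hasattr(model, "predict_proba"):
        pos_col = list(model.classes_).index(positive)
        scores = model.predict_proba(X.to_numpy(float))[:, pos_col]
    return metrics_from_predictions(np.asarray(y), pred, scores, positive)


def pca_scores(matrix: pd.DataFrame,
               n_components: Optional[int] = None
               ) -> Tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Unit-variance-scaled PCA: scores, explained-variance fractions, loadings.

    Zero-variance variables are dropped with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two variables")
    sd = matrix.std(ddof=1)
    keep = sd[sd > 0].index
    dropped = [c for c in matrix.columns if c not in set(keep)]
    if dropped:
        warnings.warn(f"dropping zero-variance variables: {dropped}")
    X = matrix.loc[:, keep]
    Z = (X - X.mean()) / X.std(ddof=1)
    k = n_components or min(Z.shape)
    pca = PCA(n_components=min(k, min(Z.shape)))
    scores = pca.fit_transform(Z.to_numpy(float))
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=matrix.index, columns=comp_names),
            pca.explained_variance_ratio_,
            pd.DataFrame(pca.components_.T, index=keep, columns=comp_names))


def run_model_battery(
    features_discovery: pd.DataFrame,
    features_validation: pd.DataFrame,
    metadata_discovery: pd.DataFrame,
    metadata_validation: pd.DataFrame,
    y_discovery: pd.Series,
    y_validation: pd.Series,
    selected: Sequence[str],
    model_type: str = "random_forest",
    n_trees: int = 500,
    seed: int = 0,
    blocks_list: Optional[List[Tuple[str, ...]]] = None,
) -> pd.DataFrame:
    """Train/evaluate every variable-block combination; one metrics row each.

    Block combinations that need metabolites are dropped (with a warning)
    when the selected set is empty — the hormone/demographic rows remain.
    """
    rows = []
    for blocks in (blocks_list or TABLE_BLOCKS):
        if "metabolites" in blocks and not list(selected):
            warnings.warn(f"skipping model {'+'.join(blocks)}: empty "
                          f"selected metabolite set")
            continue
        spec = ModelSpec(blocks=tuple(blocks), model_type=model_type,
                         n_trees=n_trees, seed=seed)
        Xd = assemble_design(blocks, metadata_discovery,
                             features_discovery, selected)
        Xv = assemble_design(blocks, metadata_validation,
                             features_validation, selected)
        model = train_model(Xd, y_discovery, spec)
        metrics = evaluate(model, Xv.loc[:, Xd.columns], y_validation)
        rows.append({"model": spec.name, **metrics.as_row()})
    return pd.DataFrame(rows)
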