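"""Orchestration: simulate → preprocess → stats → select → model → report.

One YAML config file drives every stage; a single root seed is expanded
into per-stage seeds; each stage consumes and produces only declared
files under the run directory and records its sample/feature counts in a
run manifest that, together with the config snapshot, suffices to re-run
the analysis bit-identically.

In the default ``strict`` leakage mode the discovery/validation split is
drawn immediately after sample-level QC, and every data-driven
preprocessing parameter (per-bin minimum positives, CRS reduction, PQN
reference, batch adjustments) is estimated on the discovery samples and
applied frozen to the validation samples.  The ``pooled`` mode
instead estimates those parameters on the full matrix before splitting,
reproducing the original ordering.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .modeling import pca_scores, run_model_battery
from .preprocess import Preprocessor, annotation_rate, qc_filter_fwhm
from .selection import (SplitSpec, StabilityConfig, split_cohort,
                        stability_select, univariate_gate)
from .simulate import SimConfig, cohort_to_frame, generate_cohort, generate_spectra
from .stats import cohort_table, covariate_variance_screen, fit_moderated, \
    spearman_screen

__all__ = ["ConfigError", "DEFAULT_CONFIG", "load_config", "validate_config",
           "run_pipeline", "run_stage", "report", "STAGES"]

STAGES = ["simulate", "preprocess", "stats", "select", "model", "report"]

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "leakage": "strict",                      # strict | pooled
    "simulate": {},                           # SimConfig overrides
    "preprocess": {
        "qc_k_sd": 2.0,
        "replace_factor": 0.2,
        "crs_method": "pearson",
        "batch_method": "eb",
    },
    "stats": {
        "covariates": ["age", "bmi", "gestational_age"],
        "alpha": 0.05,
    },
    "split": {
        "validation_fraction": 0.2,
        "stratify_by": "outcome",
    },
    "select": {
        "n_folds": 10,
        "n_rounds": 100,
        "round_threshold": 0.8,
        "fold_threshold": 8,
        "lambda_rule": "1se",
        "family": "gaussian",
    },
    "model": {
        "model_type": "random_forest",
        "n_trees": 500,
    },
}


class ConfigError(ValueError):
    """Configuration violates the schema; message names key and constraint."""


def _merge(base: Dict, override: Dict) -> Dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Dict] = None) -> Dict:
    """Read a YAML config, merge onto defaults, validate."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root: must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Dict) -> None:
    def fail(key: str, constraint: str):
        raise ConfigError(f"config key {key!r}: {constraint}")

    if not isinstance(cfg.get("seed"), int):
        fail("seed", "must be an integer")
    if cfg.get("leakage") not in {"strict", "pooled"}:
        fail("leakage", "must be 'strict' or 'pooled'")
    frac = cfg["split"].get("validation_fraction")
    if not isinstance(frac, (int, float)) or not (0 < frac < 1):
        fail("split.validation_fraction", "must lie strictly between 0 and 1")
    pp = cfg["preprocess"]
    if pp.get("batch_method") not in {"eb", "standardize", "none"}:
        fail("preprocess.batch_method", "must be 'eb', 'standardize' or 'none'")
    if pp.get("qc_k_sd") is not None and pp["qc_k_sd"] < 0:
        fail("preprocess.qc_k_sd", "must be nonnegative (or null to skip)")
    if not (0 < pp.get("replace_factor", 0.2) <= 1):
        fail("preprocess.replace_factor", "must lie in (0, 1]")
    sel = cfg["select"]
    if not (0 < sel.get("round_threshold", 0.8) <= 1):
        fail("select.round_threshold", "must lie in (0, 1]")
    if sel.get("fold_threshold", 8) >= sel.get("n_folds", 10):
        fail("select.fold_threshold", "must be smaller than select.n_folds")
    if sel.get("lambda_rule", "1se") not in {"1se", "min"}:
        fail("select.lambda_rule", "must be '1se' or 'min'")
    if sel.get("family", "gaussian") not in {"gaussian", "binomial"}:
        fail("select.family", "must be 'gaussian' or 'binomial'")
    alpha = cfg["stats"].get("alpha", 0.05)
    if not (0 < alpha < 1):
        fail("stats.alpha", "must lie strictly between 0 and 1")
    md = cfg["model"]
    if md.get("model_type", "random_forest") not in {"random_forest", "glm"}:
        fail("model.model_type", "must be 'random_forest' or 'glm'")
    if md.get("n_trees", 500) < 1:
        fail("model.n_trees", "must be a positive integer")


def _stage_seeds(seed: int) -> Dict[str, int]:
    vals = np.random.default_rng(int(seed)).integers(0, 2 ** 31 - 1, len(STAGES))
    return {s: int(v) for s, v in zip(STAGES, vals)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **kw)


class Run:
    """A run directory plus its (incrementally built) manifest."""

    def __init__(self, outdir: str | Path, config: Dict):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.seeds = _stage_seeds(config["seed"])
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"version": __version__, "config": config,
                             "stage_seeds": self.seeds, "stages": {}}
        # config/seed may differ from a stale manifest; trust the new ones
        self.manifest["config"] = config
        self.manifest["stage_seeds"] = self.seeds
        self.manifest["version"] = __version__

    def path(self, name: str) -> Path:
        return self.outdir / name

    def record(self, stage: str, files: List[Path],
               counts: Dict[str, List[int]] | List, notes: Dict | None = None):
        self.manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "counts": counts,
            **({"notes": notes} if notes else {}),
        }
        self.manifest_path.write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------------- stages


def stage_simulate(run: Run) -> None:
    cfg = run.config
    sim = SimConfig(**cfg["simulate"]).with_seed(run.seeds["simulate"])
    cohort = generate_cohort(sim)
    matrix, annotation = generate_spectra(cohort, sim)
    paths = [run.path("cohort.csv"), run.path("matrix.tsv"),
             run.path("annotation.tsv")]
    _write_csv(cohort_to_frame(cohort), paths[0])
    _write_csv(matrix, paths[1], sep="\t")
    _write_csv(annotation, paths[2], sep="\t")
    run.record("simulate", paths,
               {"samples": len(cohort), "bins": matrix.shape[1],
                "annotated_bins": len(annotation),
                "annotation_rate_pct": annotation_rate(
                    len(annotation), matrix.shape[1])})


def _read_inputs(run: Run):
    cohort = pd.read_csv(run.path("cohort.csv"), index_col=0)
    matrix = pd.read_csv(run.path("matrix.tsv"), sep="\t", index_col=0)
    annotation = pd.read_csv(run.path("annotation.tsv"), sep="\t", index_col=0)
    return cohort, matrix, annotation


def stage_preprocess(run: Run) -> None:
    cfg = run.config
    pp = cfg["preprocess"]
    cohort, matrix, annotation = _read_inputs(run)

    kept = qc_filter_fwhm(cohort["fwhm"], k=pp["qc_k_sd"]) \
        if pp["qc_k_sd"] is not None else list(cohort.index)
    excluded = [s for s in cohort.index if s not in set(kept)]
    exclusions = pd.DataFrame(
        {"sample_id": excluded,
         "rule": [f"fwhm > mean + {pp['qc_k_sd']} SD"] * len(excluded)})
    cohort_q = cohort.loc[kept]
    matrix_q = matrix.loc[kept]

    spec = SplitSpec(validation_fraction=cfg["split"]["validation_fraction"],
                     stratify_by=cfg["split"]["stratify_by"],
                     seed=run.seeds["preprocess"])
    disc, val = split_cohort(cohort_q, spec)
    split_df = pd.DataFrame({"sample_id": list(cohort_q.index)})
    split_df["set"] = ["validation" if s in set(val) else "discovery"
                       for s in split_df["sample_id"]]

    prep = Preprocessor(k_sd=None, replace_factor=pp["replace_factor"],
                        crs_method=pp["crs_method"],
                        batch_method=pp["batch_method"])
    if cfg["leakage"] == "strict":
        prep.fit(matrix_q.loc[disc], annotation,
                 fwhm=cohort_q.loc[disc, "fwhm"],
                 batch=cohort_q.loc[disc, "batch"],
                 covariates=cohort_q.loc[disc, ["binary_label"]])
        refined_disc = prep.matrix_
        refined_val = prep.transform(matrix_q.loc[val],
                                     fwhm=cohort_q.loc[val, "fwhm"],
                                     batch=cohort_q.loc[val, "batch"])
    else:
        prep.fit(matrix_q, annotation, fwhm=cohort_q["fwhm"],
                 batch=cohort_q["batch"],
                 covariates=cohort_q[["binary_label"]])
        refined_disc = prep.matrix_.loc[disc]
        refined_val = prep.matrix_.loc[[s for s in val
                                        if s in prep.matrix_.index]]

    crs_rows = []
    for met, passed in prep.crs_.passed.items():
        best = max(s for _, s in prep.crs_.scores[met])
        crs_rows.append({"metabolite": met,
                         "representative": prep.crs_.representative[met],
                         "best_crs": best, "passed": passed,
                         "n_bins": len(prep.crs_.scores[met])})
    crs_df = pd.DataFrame(crs_rows).sort_values("metabolite")
    log_df = pd.DataFrame(prep.log_, columns=["stage", "n_samples", "n_bins"])

    paths = {
        "split": run.path("split.csv"),
        "exclusions": run.path("qc_exclusions.csv"),
        "disc": run.path("refined_discovery.tsv"),
        "val": run.path("refined_validation.tsv"),
        "crs": run.path("crs.csv"),
        "log": run.path("preprocess_log.csv"),
    }
    _write_csv(split_df, paths["split"], index=False)
    _write_csv(exclusions, paths["exclusions"], index=False)
    _write_csv(refined_disc, paths["disc"], sep="\t")
    _write_csv(refined_val, paths["val"], sep="\t")
    _write_csv(crs_df, paths["crs"], index=False)
    _write_csv(log_df, paths["log"], index=False)
    run.record("preprocess", list(paths.values()), {
        "qc_excluded": len(excluded),
        "discovery": len(disc), "validation": len(val),
        "bins_after_crs": refined_disc.shape[1],
        "crs_passing_score": prep.crs_.passing_score,
        "stage_log": prep.log_,
    })


def _read_refined(run: Run):
    cohort = pd.read_csv(run.path("cohort.csv"), index_col=0)
    disc = pd.read_csv(run.path("refined_discovery.tsv"), sep="\t", index_col=0)
    val = pd.read_csv(run.path("refined_validation.tsv"), sep="\t", index_col=0)
    return cohort, disc, val


def stage_stats(run: Run) -> None:
    cfg = run.config
    cohort, disc, val = _read_refined(run)
    used = cohort.loc[list(disc.index) + list(val.index)]
    table = cohort_table(used)
    spear = spearman_screen(used)
    meta_cols = ["age", "bmi", "gestational_age", "bhcg", "progesterone",
                 "batch"]
    _, screen = covariate_variance_screen(disc, cohort.loc[disc.index,
                                                           meta_cols])
    de = fit_moderated(disc, cohort.loc[disc.index, "binary_label"],
                       covariates=cohort.loc[disc.index,
                                             cfg["stats"]["covariates"]])
    de_table = de.table.copy()
    de_table.index.name = "bin_id"
    paths = {
        "cohort_table": run.path("cohort_table.csv"),
        "spearman": run.path("spearman.csv"),
        "variance_screen": run.path("variance_screen.csv"),
        "de": run.path("de.csv"),
    }
    _write_csv(table, paths["cohort_table"], index=False)
    _write_csv(spear, paths["spearman"], index=False)
    _write_csv(screen, paths["variance_screen"])
    _write_csv(de_table, paths["de"])
    run.record("stats", list(paths.values()), {
        "bins_tested": len(de_table),
        "significant_5pct_fdr": int((de_table["q"] < cfg["stats"]["alpha"]).sum()),
        "prior_df": de.prior_df,
    })


def stage_select(run: Run) -> None:
    cfg = run.config
    cohort, disc, _ = _read_refined(run)
    de_table = pd.read_csv(run.path("de.csv"), index_col=0)
    gated = univariate_gate(de_table, alpha=cfg["stats"]["alpha"])
    paths = {"stability": run.path("stability.csv"),
             "selected": run.path("selected.txt")}
    if gated:
        sc = StabilityConfig(
            n_folds=cfg["select"]["n_folds"],
            n_rounds=cfg["select"]["n_rounds"],
            round_threshold=cfg["select"]["round_threshold"],
            fold_threshold=cfg["select"]["fold_threshold"],
            lambda_rule=cfg["select"]["lambda_rule"],
            family=cfg["select"]["family"],
            seed=run.seeds["select"])
        result = stability_select(disc.loc[:, gated],
                                  cohort.loc[disc.index, "binary_label"], sc)
        stab = result.fold_frequencies.copy()
        stab["n_folds_passed"] = result.n_folds_passed
        stab["selected"] = [f in set(result.selected) for f in stab.index]
        selected = result.selected
    else:
        stab = pd.DataFrame(columns=["n_folds_passed", "selected"])
        selected = []
    stab.index.name = "bin_id"
    _write_csv(stab, paths["stability"])
    paths["selected"].write_text("".join(f"{s}\n" for s in selected))
    run.record("select", list(paths.values()), {
        "gated": len(gated), "selected": len(selected)})


def stage_model(run: Run) -> None:
    cfg = run.config
    cohort, disc, val = _read_refined(run)
    selected = [s for s in
                run.path("selected.txt").read_text().splitlines() if s]
    meta_d = cohort.loc[disc.index]
    meta_v = cohort.loc[val.index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = run_model_battery(
            disc, val, meta_d, meta_v,
            meta_d["binary_label"], meta_v["binary_label"], selected,
            model_type=cfg["model"]["model_type"],
            n_trees=cfg["model"]["n_trees"], seed=run.seeds["model"])

    pca_input = pd.concat(
        [disc.loc[:, selected],
         np.log2(meta_d[["bhcg", "progesterone"]].astype(float))], axis=1) \
        if selected else np.log2(meta_d[["bhcg", "progesterone"]].astype(float))
    scores, evr, _ = pca_scores(pca_input)
    scores = scores.iloc[:, :2].copy()
    scores["outcome"] = meta_d["outcome"]
    evr_df = pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(evr))],
                           "explained_variance_fraction": evr})

    paths = {"metrics": run.path("metrics.csv"),
             "pca_scores": run.path("pca_scores.csv"),
             "pca_variance": run.path("pca_variance.csv")}
    _write_csv(metrics, paths["metrics"], index=False)
    _write_csv(scores, paths["pca_scores"])
    _write_csv(evr_df, paths["pca_variance"], index=False)
    run.record("model", list(paths.values()), {
        "models": len(metrics), "n_selected_features": len(selected)})


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3g}") -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        cells = [floatfmt.format(v) if isinstance(v, float) and np.isfinite(v)
                 else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def report(outdir: str | Path) -> str:
    """Render the run summary (deterministic markdown); write report.md."""
    outdir = Path(outdir)
    needed = ["cohort_table.csv", "de.csv", "stability.csv", "selected.txt",
              "metrics.csv"]
    missing = [n for n in needed if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")
    cohort_tab = pd.read_csv(outdir / "cohort_table.csv")
    de = pd.read_csv(outdir / "de.csv", index_col=0).sort_values("p")
    selected = [s for s in (outdir / "selected.txt").read_text().splitlines()
                if s]
    metrics = pd.read_csv(outdir / "metrics.csv")

    parts = ["# Run report", "", "## Cohort demographics", "",
             _md_table(cohort_tab), "", "## Top differential signals", "",
             _md_table(de.head(15).reset_index()), "",
             "## Stability-selected signals", ""]
    if selected:
        parts += [f"- {s}" for s in selected]
    else:
        parts += ["(none selected — models fall back to hormone and "
                  "demographic blocks only)"]
    parts += ["", "## Validation performance", "", _md_table(metrics), ""]
    text = "\n".join(parts)
    (outdir / "report.md").write_text(text)
    return text


def stage_report(run: Run) -> None:
    report(run.outdir)
    run.record("report", [run.path("report.md")], {})


_STAGE_FN = {"simulate": stage_simulate, "preprocess": stage_preprocess,
             "stats": stage_stats, "select": stage_select,
             "model": stage_model, "report": stage_report}


def run_stage(name: str, config: Dict, outdir: str | Path) -> Run:
    if name not in _STAGE_FN:
        raise ConfigError(f"config key 'stage': must be one of {STAGES}")
    run = Run(outdir, config)
    _STAGE_FN[name](run)
    return run


def run_pipeline(config: Dict, outdir: str | Path) -> Dict:
    """Execute all stages in order; returns the manifest dict."""
    run = Run(outdir, config)
    for name in STAGES:
        _STAGE_FN[name](run)
    return run.manifest
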