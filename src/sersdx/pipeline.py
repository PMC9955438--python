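"""End-to-end pipeline driver: simulate -> preprocess -> fit -> validate -> report.

A :class:`RunConfig` (constructible from YAML/JSON) fully determines a
run; every stochastic step derives from its single seed, and a
``manifest.json`` with the echoed configuration, package version and
per-stage log is written next to the outputs so that any run can be
replayed bit-identically from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .dataset import SpectrumSet, read_spectrumset
from .synthetic import CohortConfig, generate_cohort
from .preprocess import PreprocessConfig, preprocess_pipeline
from .opls import fit_opls, predict_opls, scores_for_plot
from .pcalda import fit_pcalda, predict_pcalda
from .peaks import anova_peaks
from .validate import (
    ModelSpec,
    confusion_metrics,
    kfold_cv,
    one_vs_rest_auc,
    permutation_test,
    roc_tables,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; ``seed`` drives all randomness."""

    output_dir: str = "sersdx_run"
    input_csv: str | None = None  # if None, simulate a cohort
    simulate: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: str = "both"  # "opls" | "pcalda" | "both"
    class_order: list[str] | None = None
    n_predictive: int | None = None
    n_orthogonal: int | None = 1
    folds: int = 10
    n_permutations: int = 100
    run_permutation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("opls", "pcalda", "both"):
            raise ValueError(f"model must be opls|pcalda|both, got {self.model!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            raw["simulate"] = CohortConfig(**raw["simulate"])
        if "preprocess" in raw and isinstance(raw["preprocess"], dict):
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def echo(self) -> dict[str, Any]:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return plain(self)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the result bundle.

    Writes (under ``config.output_dir``): the cohort CSV (if simulated),
    the preprocessed CSV, the peak ANOVA table, model JSONs, score and
    ROC tables, cross-validation reports, the permutation record and the
    manifest.  Any stage failure aborts with the stage name in the error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []
    bundle: dict[str, Any] = {}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        stage_log.append(name)

    try:
        stage("load")
        if config.input_csv is not None:
            sset = read_spectrumset(config.input_csv)
        else:
            cfg = dataclasses.replace(config.simulate, seed=config.seed)
            sset, truth = generate_cohort(cfg)
            sset.to_csv(out / "cohort.csv")
            truth.to_json(out / "ground_truth.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    order = config.class_order or sset.class_order()

    try:
        stage("preprocess")
        trace: list = []
        pset = preprocess_pipeline(sset, config.preprocess, trace=trace)
        pset.to_csv(out / "preprocessed.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        stage("peaks")
        peak_table = anova_peaks(pset, class_order=order)
        peak_table.to_csv(out / "peak_anova.csv", index=False)
        bundle["peak_table"] = peak_table
    except Exception as exc:
        raise RuntimeError(f"stage 'peaks' failed: {exc}") from exc

    X, labels = pset.intensities, pset.labels
    summaries = []

    if config.model in ("opls", "both"):
        try:
            stage("fit_opls")
            model = fit_opls(
                X,
                labels,
                n_predictive=config.n_predictive,
                n_orthogonal=config.n_orthogonal,
                cv_folds=config.folds,
                seed=config.seed,
                class_order=order,
                sample_ids=pset.sample_ids,
            )
            model.to_json(out / "opls_model.json")
            table, ellipse = scores_for_plot(model)
            table.to_csv(out / "opls_scores.csv", index=False)
            (out / "opls_score_ellipse.json").write_text(json.dumps(ellipse, indent=2))
            fit_scores, fit_pred = predict_opls(model, X)
            fit_report = confusion_metrics(labels, fit_pred, order)
            fit_report.auc = one_vs_rest_auc(fit_scores, labels, order)
            for cls, tab in roc_tables(fit_scores, labels, order).items():
                tab.to_csv(out / f"opls_roc_{cls}.csv", index=False)
            cv = kfold_cv(
                X,
                labels,
                ModelSpec(
                    "opls",
                    {
                        "n_predictive": config.n_predictive,
                        "n_orthogonal": config.n_orthogonal or 1,
                    },
                ),
                folds=config.folds,
                seed=config.seed,
                class_order=order,
            )
            bundle["opls"] = {
                "model": model,
                "fit_report": fit_report,
                "cv": cv,
            }
            summaries.append(("opls", fit_report, cv.report))
            fit_report.summary().to_csv(out / "opls_fit_metrics.csv", index=False)
            cv.report.summary().to_csv(out / "opls_cv_metrics.csv", index=False)
            cv.report.to_frame().to_csv(out / "opls_cv_confusion.csv")
        except Exception as exc:
            raise RuntimeError(f"stage 'fit_opls' failed: {exc}") from exc

        if config.run_permutation:
            try:
                stage("permutation")
                perm = permutation_test(
                    X,
                    labels,
                    ModelSpec(
                        "opls",
                        {
                            "n_predictive": config.n_predictive,
                            "n_orthogonal": config.n_orthogonal or 1,
                        },
                    ),
                    n_perm=config.n_permutations,
                    seed=config.seed,
                    cv_folds=config.folds,
                    class_order=order,
                )
                perm.to_frame().to_csv(out / "permutation.csv", index=False)
                bundle["permutation"] = perm
            except Exception as exc:
                raise RuntimeError(f"stage 'permutation' failed: {exc}") from exc

    if config.model in ("pcalda", "both"):
        try:
            stage("fit_pcalda")
            pl_model = fit_pcalda(X, labels, class_order=order)
            pl_model.to_json(out / "pcalda_model.json")
            pl_scores, pl_pred = predict_pcalda(pl_model, X)
            pl_report = confusion_metrics(labels, pl_pred, order)
            pl_report.auc = one_vs_rest_auc(pl_scores, labels, order)
            pl_cv = kfold_cv(
                X,
                labels,
                ModelSpec("pcalda"),
                folds=config.folds,
                seed=config.seed,
                class_order=order,
            )
            bundle["pcalda"] = {"model": pl_model, "fit_report": pl_report, "cv": pl_cv}
            summaries.append(("pcalda", pl_report, pl_cv.report))
            pl_report.summary().to_csv(out / "pcalda_fit_metrics.csv", index=False)
            pl_cv.report.summary().to_csv(out / "pcalda_cv_metrics.csv", index=False)
            pl_cv.report.to_frame().to_csv(out / "pcalda_cv_confusion.csv")
        except Exception as exc:
            raise RuntimeError(f"stage 'fit_pcalda' failed: {exc}") from exc

    try:
        stage("report")
        rows = []
        for name, fit_report, cv_report in summaries:
            rows.append(
                {
                    "model": name,
                    "fit_accuracy_pct": fit_report.accuracy_pct,
                    "cv_accuracy_pct": cv_report.accuracy_pct,
                    **{
                        f"cv_sensitivity_{c}_pct": cv_report.sensitivity_pct[c]
                        for c in order
                    },
                    **{
                        f"cv_specificity_{c}_pct": cv_report.specificity_pct[c]
                        for c in order
                    },
                }
            )
        if rows:
            import pandas as pd

            summary = pd.DataFrame(rows)
            summary.to_csv(out / "model_comparison.csv", index=False)
            bundle["summary"] = summary
        manifest = {
            "sersdx_version": __version__,
            "config": config.echo(),
            "class_order": list(order),
            "n_samples": int(sset.n_samples),
            "preprocess_trace": [
                {"stage": name, "params": params} for name, params in trace
            ],
            "stages": stage_log,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc

    return bundle
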