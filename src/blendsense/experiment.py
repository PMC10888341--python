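"""End-to-end experiments: binary and six-class classification of blends,
and per-oil blend-level regression, each reported over three stages —
calibration, y-randomization and test.

One Kennard–Stone split is computed per experiment and shared by whatever
model runs on it, so linear and kernel models are compared on identical
calibration/test sets. Regression targets are expressed in percent blend
(0–50), the scale on which RMSE is reported.

An :class:`IndexAudit` records which dataset rows each stage materializes;
tuning and y-randomization must only ever touch calibration rows, and the
audit makes that checkable after the fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core import ConfigurationError, Dataset, Illuminant, OilIdentity, Task
from .ingest import read_dataset
from .models import (
    HyperparameterGrid,
    fit_lda,
    fit_lssvm,
    fit_lssvm_classifier,
    fit_mlr,
    predict_lda,
    predict_lssvm,
    predict_lssvm_classifier,
    predict_mlr,
    tune_lssvm,
)
from .partition import SplitResult, split_dataset
from .synthetic import (
    SyntheticConfig,
    default_config,
    generate_calibration_dataset,
    generate_classification_dataset,
)
from .validation import (
    METRIC_FIELDS,
    OVERALL,
    ClassificationReport,
    ClassMetrics,
    RegressionMetrics,
    YRandResult,
    classification_report,
    crp_squared,
    r0_squared,
    r_squared,
    regression_metrics,
    rm_squared,
    rmse,
    y_randomization,
)

BINARY_LABELS = ["pure", "blended"]
MULTICLASS_LABELS = ["pure"] + [o.value for o in OilIdentity.adulterants()]

STAGES = ("calibration", "y_randomization", "test")


class IndexAudit:
    """Records, per pipeline stage, the dataset row indices materialized."""

    def __init__(self) -> None:
        self.accesses: dict[str, set[int]] = {}

    def take(self, stage: str, X: np.ndarray, indices) -> np.ndarray:
        ix = list(indices)
        self.accesses.setdefault(stage, set()).update(int(i) for i in ix)
        return X[ix]

    def rows(self, stage: str) -> frozenset[int]:
        return frozenset(self.accesses.get(stage, set()))


@dataclass(frozen=True)
class ExperimentConfig:
    task: Task
    model: str  # {lda, mlr, lssvm}
    illuminant: Illuminant = Illuminant.WHITE
    split_fraction: float = 0.7
    calibration_size_override: int | None = None
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    n_permutations: int = 100
    seed: int = 0
    input_path: str | None = None  # None -> synthetic data
    synthetic: SyntheticConfig | None = None
    #: Re-tune hyperparameters inside each y-randomization refit (the same
    #: protocol as the real model); switch off to freeze the chosen pair.
    retune_per_permutation: bool = True
    adulterant: OilIdentity | None = None  # regression only

    def __post_init__(self) -> None:
        if self.model not in {"lda", "mlr", "lssvm"}:
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.task is Task.REGRESSION and self.model == "lda":
            raise ConfigurationError("LDA is a classifier; not valid for regression")
        if self.task is not Task.REGRESSION and self.model == "mlr":
            raise ConfigurationError("MLR is a regressor; not valid for classification")

    def synthetic_config(self) -> SyntheticConfig:
        if self.synthetic is not None:
            return self.synthetic
        return default_config(seed=self.seed)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    split: SplitResult
    reports: dict[str, object]  # stage -> ClassificationReport | RegressionMetrics
    yrand: YRandResult
    hyperparameters: dict[str, float]
    audit: IndexAudit
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# classification


def _flatten_report(rep: ClassificationReport) -> dict[str, float]:
    flat = {f"{OVERALL}.{f}": getattr(rep.overall, f) for f in METRIC_FIELDS}
    for lab, m in rep.per_class.items():
        flat.update({f"{lab}.{f}": getattr(m, f) for f in METRIC_FIELDS})
    return flat


def _unflatten_report(
    flat: Mapping[str, float], labels: list[str], stage: str
) -> ClassificationReport:
    per_class = {
        lab: ClassMetrics(**{f: flat[f"{lab}.{f}"] for f in METRIC_FIELDS})
        for lab in labels
    }
    overall = ClassMetrics(**{f: flat[f"{OVERALL}.{f}"] for f in METRIC_FIELDS})
    return ClassificationReport(per_class=per_class, overall=overall, stage=stage)


def _classification_dataset(cfg: ExperimentConfig) -> Dataset:
    if cfg.input_path is not None:
        return read_dataset(cfg.input_path, task=cfg.task)
    return generate_classification_dataset(cfg.synthetic_config(), cfg.illuminant)


def _run_classification(cfg: ExperimentConfig, labels: list[str]) -> ExperimentResult:
    ds = _classification_dataset(cfg)
    y_all = np.asarray(
        ds.binary_labels() if cfg.task is Task.BINARY else ds.multiclass_labels()
    )
    present = set(y_all.tolist())
    missing = [lab for lab in labels if lab not in present]
    if missing:
        raise ValueError(f"dataset lacks class(es): {', '.join(missing)}")

    X_all = ds.feature_matrix()
    split = split_dataset(ds, cfg.split_fraction, cfg.calibration_size_override)
    audit = IndexAudit()
    X_cal = audit.take("fit", X_all, split.calibration_indices)
    y_cal = y_all[list(split.calibration_indices)]
    X_test = audit.take("test", X_all, split.test_indices)
    y_test = y_all[list(split.test_indices)]

    hyper: dict[str, float] = {}
    if cfg.model == "lssvm":
        audit.take("tuning", X_all, split.calibration_indices)
        gamma, sigma2 = tune_lssvm(X_cal, y_cal, cfg.grid, "classification")
        hyper = {"gamma": gamma, "sigma2": sigma2}
        machine = fit_lssvm_classifier(X_cal, y_cal, gamma, sigma2, class_order=labels)
        pred_cal = predict_lssvm_classifier(machine, X_cal)
        pred_test = predict_lssvm_classifier(machine, X_test)
    else:  # lda
        model = fit_lda(X_cal, y_cal)
        pred_cal = predict_lda(model, X_cal)
        pred_test = predict_lda(model, X_test)

    rep_cal = classification_report(y_cal, pred_cal, labels, stage="calibration")
    rep_test = classification_report(y_test, pred_test, labels, stage="test")

    def fit_score(Xp: np.ndarray, yp: np.ndarray) -> dict[str, float]:
        if cfg.model == "lssvm":
            if cfg.retune_per_permutation:
                g, s2 = tune_lssvm(Xp, yp, cfg.grid, "classification")
            else:
                g, s2 = hyper["gamma"], hyper["sigma2"]
            mach = fit_lssvm_classifier(Xp, yp, g, s2, class_order=labels)
            pred = predict_lssvm_classifier(mach, Xp)
        else:
            mod = fit_lda(Xp, yp)
            pred = predict_lda(mod, Xp)
        return _flatten_report(classification_report(yp, pred, labels))

    audit.take("y_randomization", X_all, split.calibration_indices)
    yrand = y_randomization(
        fit_score, X_cal, y_cal, n_permutations=cfg.n_permutations, seed=cfg.seed
    )
    rep_yrand = _unflatten_report(yrand.mean_scores, labels, stage="y_randomization")

    warnings_list = []
    if yrand.n_failures:
        warnings_list.append(f"{yrand.n_failures} y-randomization refits failed")
    return ExperimentResult(
        config=cfg,
        split=split,
        reports={"calibration": rep_cal, "y_randomization": rep_yrand, "test": rep_test},
        yrand=yrand,
        hyperparameters=hyper,
        audit=audit,
        warnings=warnings_list,
    )


def run_binary(cfg: ExperimentConfig) -> ExperimentResult:
    """Pure-vs-blended classification (labels derived from fraction == 0)."""
    if cfg.task is not Task.BINARY:
        cfg = replace(cfg, task=Task.BINARY)
    return _run_classification(cfg, BINARY_LABELS)


def run_multiclass(cfg: ExperimentConfig) -> ExperimentResult:
    """Six-class classification: pure avocado plus five adulterant classes."""
    if cfg.task is not Task.MULTICLASS:
        cfg = replace(cfg, task=Task.MULTICLASS)
    return _run_classification(cfg, MULTICLASS_LABELS)


# ---------------------------------------------------------------------------
# regression


def run_regression(
    cfg: ExperimentConfig, adulterant: OilIdentity | None = None
) -> ExperimentResult:
    """Blend-level quantification for one adulterant, in percent (0-50)."""
    adulterant = adulterant or cfg.adulterant
    if adulterant is None:
        raise ConfigurationError("regression needs an adulterant")
    if cfg.task is not Task.REGRESSION:
        cfg = replace(cfg, task=Task.REGRESSION)

    if cfg.input_path is not None:
        ds = read_dataset(cfg.input_path, task=Task.REGRESSION)
    else:
        ds = generate_calibration_dataset(
            adulterant, cfg.synthetic_config(), cfg.illuminant
        )
    if len(set(ds.fractions().tolist())) < 3:
        raise ValueError("regression needs at least 3 distinct fraction levels")

    X_all = ds.feature_matrix()
    y_all = ds.fractions() * 100.0  # percent blend
    split = split_dataset(ds, cfg.split_fraction, cfg.calibration_size_override)
    audit = IndexAudit()
    X_cal = audit.take("fit", X_all, split.calibration_indices)
    y_cal = y_all[list(split.calibration_indices)]
    X_test = audit.take("test", X_all, split.test_indices)
    y_test = y_all[list(split.test_indices)]

    hyper: dict[str, float] = {}
    if cfg.model == "lssvm":
        audit.take("tuning", X_all, split.calibration_indices)
        gamma, sigma2 = tune_lssvm(X_cal, y_cal, cfg.grid, "regression")
        hyper = {"gamma": gamma, "sigma2": sigma2}
        model = fit_lssvm(X_cal, y_cal, gamma, sigma2, "regression")
        pred_cal = predict_lssvm(model, X_cal)
        pred_test = predict_lssvm(model, X_test)
    else:  # mlr
        model = fit_mlr(X_cal, y_cal)
        pred_cal = predict_mlr(model, X_cal)
        pred_test = predict_mlr(model, X_test)

    met_cal = regression_metrics(y_cal, pred_cal)
    met_test = regression_metrics(y_test, pred_test, with_rm2=True)

    def fit_score(Xp: np.ndarray, yp: np.ndarray) -> dict[str, float]:
        yp = np.asarray(yp, float)
        if cfg.model == "lssvm":
            if cfg.retune_per_permutation:
                g, s2 = tune_lssvm(Xp, yp, cfg.grid, "regression")
            else:
                g, s2 = hyper["gamma"], hyper["sigma2"]
            mod = fit_lssvm(Xp, yp, g, s2, "regression")
            pred = predict_lssvm(mod, Xp)
        else:
            mod = fit_mlr(Xp, yp)
            pred = predict_mlr(mod, Xp)
        return {"RMSE": rmse(yp, pred), "R2": r_squared(yp, pred)}

    audit.take("y_randomization", X_all, split.calibration_indices)
    yrand = y_randomization(
        fit_score, X_cal, y_cal, n_permutations=cfg.n_permutations, seed=cfg.seed
    )
    met_yrand = RegressionMetrics(
        RMSE=yrand.mean_scores.get("RMSE", float("nan")),
        R2=yrand.mean_scores.get("R2", float("nan")),
        cRp2=crp_squared(met_cal.R2, yrand.mean_scores.get("R2", float("nan"))),
    )

    warnings_list = []
    if yrand.n_failures:
        warnings_list.append(f"{yrand.n_failures} y-randomization refits failed")
    return ExperimentResult(
        config=cfg,
        split=split,
        reports={"calibration": met_cal, "y_randomization": met_yrand, "test": met_test},
        yrand=yrand,
        hyperparameters=hyper,
        audit=audit,
        warnings=warnings_list,
    )


# ---------------------------------------------------------------------------
# report rendering


_STAGE_TITLES = {
    "calibration": "calibration",
    "y_randomization": "y-rand.",
    "test": "test",
}


def _fmt(metric: str, value: float) -> str:
    # percent metrics to 1 decimal, unit-ratio metrics to 2 decimals
    if metric in ("PRE", "REC", "ACU", "ERR"):
        return f"{value:.1f}"
    if metric == "RMSE":
        return f"{value:.2f}"
    return f"{value:.2f}"


def _classification_rows(res: ExperimentResult) -> tuple[list[str], list[list[str]]]:
    first = next(iter(res.reports.values()))
    labels = list(first.per_class.keys())
    header = ["stage", "metric", OVERALL] + [lab.capitalize() for lab in labels]
    rows = []
    for stage in STAGES:
        rep = res.reports[stage]
        for metric in METRIC_FIELDS:
            row = [_STAGE_TITLES[stage], metric, _fmt(metric, getattr(rep.overall, metric))]
            row += [_fmt(metric, getattr(rep.per_class[lab], metric)) for lab in labels]
            rows.append(row)
    return header, rows


_REGRESSION_LAYOUT = {
    "calibration": ("RMSE", "R2"),
    "y_randomization": ("RMSE", "R2", "cRp2"),
    "test": ("RMSE", "R2", "Rm2"),
}


def _regression_rows(res: ExperimentResult) -> tuple[list[str], list[list[str]]]:
    header = ["stage", "metric", "value"]
    rows = []
    for stage in STAGES:
        met = res.reports[stage].as_dict()
        for metric in _REGRESSION_LAYOUT[stage]:
            rows.append([_STAGE_TITLES[stage], metric, _fmt(metric, met[metric])])
    return header, rows


def render_report(res: ExperimentResult, format: str = "text") -> str:
    """Render the stage x metric x class grid as aligned text or CSV.

    Percent metrics print with 1 decimal and unit-ratio metrics with 2,
    the rounding used for display throughout; values inside the result
    stay at full precision. Output bytes are deterministic.
    """
    if res.config.task is Task.REGRESSION:
        header, rows = _regression_rows(res)
    else:
        header, rows = _classification_rows(res)
    if format == "csv":
        lines = [",".join(header)] + [",".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")
    widths = [max(len(h), *(len(r[i]) for r in rows)) for i, h in enumerate(header)]
    out = ["  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip()]
    out += ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows]
    return "\n".join(out) + "\n"


def result_to_dict(res: ExperimentResult) -> dict:
    """Machine-readable result summary (full precision)."""
    reports = {}
    for stage, rep in res.reports.items():
        if isinstance(rep, RegressionMetrics):
            reports[stage] = rep.as_dict()
        else:
            reports[stage] = rep.as_table()
    return {
        "task": res.config.task.value,
        "model": res.config.model,
        "illuminant": res.config.illuminant.value,
        "seed": res.config.seed,
        "adulterant": res.config.adulterant.value if res.config.adulterant else None,
        "split": {
            "calibration": list(res.split.calibration_sorted),
            "test": list(res.split.test_sorted),
            "fraction": res.split.fraction,
        },
        "hyperparameters": res.hyperparameters,
        "reports": reports,
        "y_randomization": {
            "n_permutations": res.yrand.n_permutations,
            "n_failures": res.yrand.n_failures,
            "mean_scores": res.yrand.mean_scores,
        },
        "warnings": res.warnings,
    }


def save_result(res: ExperimentResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result_to_dict(res), fh, indent=1)
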