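"""Validation statistics: confusion metrics, regression diagnostics and the
y-randomization robustness test.

Classification quality is reported per class in one-vs-rest fashion via

    PRE = TP / (TP + FP) * 100
    REC = TP / (TP + FN) * 100
    ACU = (TP + TN) / n * 100          ERR = 100 - ACU
    F1S = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

with the degenerate-denominator conventions PRE = 0 when TP+FP = 0,
REC = 0 when TP+FN = 0, F1S = 0 when 2TP+FP+FN = 0 and MCC = 0 when any
marginal factor vanishes (the value a vacuous prediction deserves: a
classifier that answers one class for everything has learned nothing, and
MCC = 0 says so even while accuracy reads as the majority share). The
"overall" row is the unweighted (macro) mean of the per-class rows.

Regression quality uses RMSE and the squared Pearson correlation R2 between
actual and predicted values, plus two external-validation statistics from
the QSAR literature:

    Rm2  = R2 * (1 - sqrt(R2 - R0^2))       (congruence; valid above 0.5)
    cRp2 = sqrt(Rcal2 * (Rcal2 - Rrand2))   (chance correlation; > 0.5 ok)

where R0^2 is the correlation of the through-origin fit of predicted on
actual, and Rrand2 the calibration R2 after refitting on shuffled targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

#: Metric field order as reported (percent metrics first, then unit ratios).
METRIC_FIELDS = ("PRE", "REC", "ACU", "ERR", "F1S", "MCC")
#: Macro-average row label in classification reports.
OVERALL = "Overall"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClassMetrics:
    PRE: float  # percent
    REC: float  # percent
    ACU: float  # percent
    ERR: float  # percent
    F1S: float  # unit ratio
    MCC: float  # in [-1, 1]

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in METRIC_FIELDS}


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, positive_label
) -> ConfusionCounts:
    """One-vs-rest confusion counts with ``positive_label`` as positive."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("cannot count an empty prediction set")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        t_pos, p_pos = t == positive_label, p == positive_label
        if t_pos and p_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    """Evaluate the six metrics on one confusion matrix."""
    if c.total == 0:
        raise ValueError("metrics undefined for an empty confusion matrix")
    tp, tn, fp, fn = (float(c.TP), float(c.TN), float(c.FP), float(c.FN))
    pre = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 0.0
    rec = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    acu = 100.0 * (tp + tn) / c.total
    err = 100.0 - acu  # exact complement of ACU
    f1s = 2.0 * tp / (2.0 * tp + fp + fn) if (2.0 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fn * fp) / math.sqrt(denom) if denom > 0 else 0.0
    return ClassMetrics(pre, rec, acu, err, f1s, mcc)


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class one-vs-rest metrics plus their macro average."""

    per_class: Mapping[str, ClassMetrics]
    overall: ClassMetrics
    stage: str = ""

    def as_table(self) -> dict[str, dict[str, float]]:
        out = {OVERALL: self.overall.as_dict()}
        out.update({lab: m.as_dict() for lab, m in self.per_class.items()})
        return out


def classification_report(
    y_true: Sequence, y_pred: Sequence, labels: Sequence[str], stage: str = ""
) -> ClassificationReport:
    """One-vs-rest metrics per label and their unweighted macro mean."""
    observed = set(y_true) | set(y_pred)
    unknown = observed - set(labels)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not covered by label list")
    per_class = {
        lab: class_metrics(confusion_counts(y_true, y_pred, lab)) for lab in labels
    }
    overall = ClassMetrics(
        **{
            f: float(np.mean([getattr(m, f) for m in per_class.values()]))
            for f in METRIC_FIELDS
        }
    )
    return ClassificationReport(per_class=per_class, overall=overall, stage=stage)


# ---------------------------------------------------------------------------
# Regression statistics


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length and nonempty")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r_squared(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between actual and predicted values."""
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length and nonempty")
    va, vp = a - a.mean(), p - p.mean()
    ssa, ssp = float(va @ va), float(vp @ vp)
    if ssa <= 0 or ssp <= 0:
        raise ValueError("R^2 undefined: a constant input has zero variance")
    r = float(va @ vp) / math.sqrt(ssa * ssp)
    return r * r


def r0_squared(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Through-origin analogue of R2 for the fit of predicted on actual.

    R0^2 = 1 - sum (p_i - k a_i)^2 / sum (p_i - mean p)^2 with the
    least-squares through-origin slope k = sum a_i p_i / sum a_i^2.
    """
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length and nonempty")
    saa = float(a @ a)
    ssp = float((p - p.mean()) @ (p - p.mean()))
    if saa <= 0 or ssp <= 0:
        raise ValueError("R0^2 undefined for zero-norm actual or constant predicted")
    k = float(a @ p) / saa
    resid = p - k * a
    return 1.0 - float(resid @ resid) / ssp


def rm_squared(R2: float, R0_2: float) -> float:
    """Rm2 = R2 * (1 - sqrt(R2 - R0^2)); a negative gap is clamped to zero."""
    gap = max(R2 - R0_2, 0.0)
    return R2 * (1.0 - math.sqrt(gap))


def crp_squared(Rcal2: float, Rrand2: float) -> float:
    """cRp2 = sqrt(Rcal2 * (Rcal2 - Rrand2)), clamped (and warned) at zero.

    A randomized-model R2 exceeding the calibration R2 would make the
    radicand negative; that situation itself signals chance correlation,
    so it is reported as 0 with a warning rather than an error.
    """
    radicand = Rcal2 * (Rcal2 - Rrand2)
    if radicand < 0:
        warnings.warn(
            "y-randomization R2 exceeds calibration R2; cRp2 clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return math.sqrt(radicand)


@dataclass(frozen=True)
class RegressionMetrics:
    """RMSE/R2 for any stage; R0_2 and Rm2 are external-validation extras,
    cRp2 belongs to the y-randomization comparison."""

    RMSE: float
    R2: float
    R0_2: float | None = None
    Rm2: float | None = None
    cRp2: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"RMSE": self.RMSE, "R2": self.R2}
        for name in ("R0_2", "Rm2", "cRp2"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


def regression_metrics(
    actual: Sequence[float],
    predicted: Sequence[float],
    with_rm2: bool = False,
) -> RegressionMetrics:
    """Bundle RMSE and R2 (plus R0^2 / Rm2 for external validation)."""
    R2 = r_squared(actual, predicted)
    out = RegressionMetrics(RMSE=rmse(actual, predicted), R2=R2)
    if with_rm2:
        R0_2 = r0_squared(actual, predicted)
        out = RegressionMetrics(
            RMSE=out.RMSE, R2=R2, R0_2=R0_2, Rm2=rm_squared(R2, R0_2)
        )
    return out


# ---------------------------------------------------------------------------
# y-randomization


@dataclass(frozen=True)
class YRandResult:
    """Scores of models refit on label-shuffled targets.

    ``per_permutation_scores`` holds one dict of named scores per successful
    permutation; ``mean_scores`` is their field-wise mean. Fit failures are
    skipped and counted in ``n_failures``.
    """

    n_permutations: int
    per_permutation_scores: list[dict[str, float]]
    mean_scores: dict[str, float]
    seed: int
    n_failures: int = 0


def y_randomization(
    fit_score_fn: Callable[[np.ndarray, np.ndarray], Mapping[str, float]],
    X: np.ndarray,
    y: Sequence,
    n_permutations: int = 100,
    seed: int = 0,
    identity: bool = False,
) -> YRandResult:
    """Refit on shuffled targets and score on the calibration samples.

    ``fit_score_fn(X, y_perm)`` must run the *same* protocol as the real
    fit — including any hyperparameter tuning — and return named scores
    evaluated on (X, y_perm). Each permutation preserves the multiset of
    ``y``. ``identity=True`` is a test hook that forces the identity
    permutation, so the scores must equal the original calibration scores.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    scores: list[dict[str, float]] = []
    failures = 0
    for _ in range(n_permutations):
        perm = np.arange(len(y)) if identity else rng.permutation(len(y))
        try:
            s = fit_score_fn(X, y[perm])
        except Exception:
            failures += 1
            continue
        scores.append({k: float(v) for k, v in s.items()})
    if scores:
        keys = scores[0].keys()
        mean_scores = {k: float(np.mean([s[k] for s in scores])) for k in keys}
    else:
        mean_scores = {}
    return YRandResult(
        n_permutations=n_permutations,
        per_permutation_scores=scores,
        mean_scores=mean_scores,
        seed=seed,
        n_failures=failures,
    )
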