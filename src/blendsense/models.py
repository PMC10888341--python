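"""Predictive models: LDA, MLR and the RBF least-squares SVM.

All three are implemented directly rather than wrapped from a machine
learning library, because their exact conventions are load-bearing here:

* LDA uses the pooled within-class covariance (divisor n - #classes) and
  *empirical* class priors. On imbalanced, heavily overlapping data the
  prior term dominates the discriminant and the classifier collapses onto
  the majority class — a failure mode the validation framework must be able
  to exhibit and measure, not hide.
* MLR is ordinary least squares with an intercept.
* LS-SVM replaces the SVM quadratic program with one (n+1)-dimensional
  linear system in the dual coefficients and a bias:

      [ 0   1^T          ] [ b     ]   [ 0 ]
      [ 1   K + I/gamma  ] [ alpha ] = [ y ]

  with K the RBF Gram matrix k(x, x') = exp(-||x - x'||^2 / (2 sigma2)).
  Decision values are f(x) = sum_i alpha_i k(x, x_i) + b; classification
  takes the sign (binary, labels encoded +/-1) or the argmax over
  one-vs-rest machines (multiclass). Every calibration point stays in the
  solution (no support-vector sparsity).

Hyperparameters (gamma, sigma2) are chosen by exhaustive grid search under
deterministic k-fold cross-validation on the calibration set only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import FittingError

Task = Literal["classification", "regression"]


# ---------------------------------------------------------------------------
# Linear discriminant analysis


@dataclass
class LDAModel:
    class_labels: list[str]
    class_means: np.ndarray  # (K, d)
    pooled_covariance: np.ndarray  # (d, d)
    priors: np.ndarray  # (K,)

    def to_dict(self) -> dict:
        return {
            "kind": "lda",
            "schema_version": 1,
            "class_labels": self.class_labels,
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            class_labels=list(d["class_labels"]),
            class_means=np.asarray(d["class_means"], float),
            pooled_covariance=np.asarray(d["pooled_covariance"], float),
            priors=np.asarray(d["priors"], float),
        )


def fit_lda(X: np.ndarray, y: Sequence[str]) -> LDAModel:
    """Fit LDA with pooled covariance and empirical priors.

    Class order is first-appearance order in ``y``; a near-singular pooled
    covariance gets a small ridge (1e-8 * trace/d) before giving up.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    labels = list(dict.fromkeys(y.tolist()))
    if len(labels) < 2:
        raise FittingError("LDA needs at least two classes")
    n, d = X.shape
    means, scatters, counts = [], [], []
    for lab in labels:
        Xk = X[y == lab]
        if len(Xk) < 2:
            raise FittingError(f"class {lab!r} has fewer than 2 samples")
        mu = Xk.mean(axis=0)
        means.append(mu)
        centred = Xk - mu
        scatters.append(centred.T @ centred)
        counts.append(len(Xk))
    pooled = sum(scatters) / (n - len(labels))
    if not np.all(np.isfinite(np.linalg.cond(pooled) * np.ones(1))) or (
        np.linalg.cond(pooled) > 1e12
    ):
        pooled = pooled + (1e-8 * np.trace(pooled) / d) * np.eye(d)
        if np.linalg.cond(pooled) > 1e12:
            raise FittingError("pooled covariance singular even after ridge")
    return LDAModel(
        class_labels=labels,
        class_means=np.vstack(means),
        pooled_covariance=pooled,
        priors=np.asarray(counts, float) / n,
    )


def lda_scores(m: LDAModel, X: np.ndarray) -> np.ndarray:
    """Linear discriminant scores x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + ln pi_k."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != m.class_means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {m.class_means.shape[1]}"
        )
    Sinv_mu = np.linalg.solve(m.pooled_covariance, m.class_means.T)  # (d, K)
    linear = X @ Sinv_mu
    const = -0.5 * np.sum(m.class_means.T * Sinv_mu, axis=0) + np.log(m.priors)
    return linear + const


def predict_lda(m: LDAModel, X: np.ndarray) -> list[str]:
    scores = lda_scores(m, X)
    return [m.class_labels[i] for i in np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# Multiple linear regression


@dataclass
class MLRModel:
    coefficients: np.ndarray  # (d,)
    intercept: float

    def to_dict(self) -> dict:
        return {
            "kind": "mlr",
            "schema_version": 1,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(np.asarray(d["coefficients"], float), float(d["intercept"]))


def fit_mlr(X: np.ndarray, y: np.ndarray) -> MLRModel:
    """Ordinary least squares with an intercept column.

    A rank-deficient design is accepted only when the minimum-norm solution
    reproduces the target exactly (noiseless mixing data is perfectly
    collinear — blends of one oil pair live on a line in feature space —
    yet is described exactly by a linear law); a deficient design that
    cannot fit its target is an error.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    if n <= d + 1:
        raise FittingError(f"need n > d + 1 = {d + 1} samples, got {n}")
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < d + 1:
        resid = design @ beta - y
        scale = max(float(np.abs(y).max()), 1.0)
        if float(np.abs(resid).max()) > 1e-8 * scale:
            raise FittingError("design matrix is rank deficient")
    return MLRModel(coefficients=beta[1:], intercept=float(beta[0]))


def predict_mlr(m: MLRModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != m.coefficients.shape[0]:
        raise ValueError("feature dimension mismatch")
    return X @ m.coefficients + m.intercept


# ---------------------------------------------------------------------------
# LS-SVM


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """Gaussian kernel matrix exp(-||a_i - b_j||^2 / (2 sigma2))."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    sq = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * sigma2))


@dataclass
class LSSVMModel:
    support_points: np.ndarray  # full calibration matrix (n, d)
    alphas: np.ndarray  # (n,)
    bias: float
    gamma: float
    sigma2: float
    task: Task

    def to_dict(self) -> dict:
        return {
            "kind": "lssvm",
            "schema_version": 1,
            "support_points": self.support_points.tolist(),
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "sigma2": self.sigma2,
            "task": self.task,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        return cls(
            support_points=np.asarray(d["support_points"], float),
            alphas=np.asarray(d["alphas"], float),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            sigma2=float(d["sigma2"]),
            task=d["task"],
        )


def fit_lssvm(
    X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float, task: Task = "regression"
) -> LSSVMModel:
    """Solve the LS-SVM dual linear system.

    For classification ``y`` must already be encoded +/-1 (one machine per
    one-vs-rest problem); for regression ``y`` is the real-valued target.
    """
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be positive")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < 2:
        raise FittingError("LS-SVM needs at least 2 samples")
    K = rbf_kernel(X, X, sigma2)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise FittingError(
            "LS-SVM system numerically singular; a smaller gamma (larger "
            "ridge 1/gamma) usually fixes this"
        ) from exc
    return LSSVMModel(
        support_points=X,
        alphas=sol[1:],
        bias=float(sol[0]),
        gamma=gamma,
        sigma2=sigma2,
        task=task,
    )


def predict_lssvm(m: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Decision values f(x) = sum_i alpha_i k(x, x_i) + bias."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != m.support_points.shape[1]:
        raise ValueError("feature dimension mismatch")
    return rbf_kernel(X, m.support_points, m.sigma2) @ m.alphas + m.bias


@dataclass
class MulticlassLSSVM:
    """One-vs-rest bank of LS-SVM machines sharing (gamma, sigma2)."""

    class_labels: list[str]
    machines: list[LSSVMModel]

    def to_dict(self) -> dict:
        return {
            "kind": "lssvm_multiclass",
            "schema_version": 1,
            "class_labels": self.class_labels,
            "machines": [m.to_dict() for m in self.machines],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MulticlassLSSVM":
        return cls(
            class_labels=list(d["class_labels"]),
            machines=[LSSVMModel.from_dict(m) for m in d["machines"]],
        )


def fit_lssvm_classifier(
    X: np.ndarray,
    y: Sequence[str],
    gamma: float,
    sigma2: float,
    class_order: Sequence[str] | None = None,
) -> MulticlassLSSVM:
    """Fit one +/-1 LS-SVM per class (one-vs-rest)."""
    y = np.asarray(y)
    labels = list(class_order) if class_order is not None else list(dict.fromkeys(y.tolist()))
    machines = []
    for lab in labels:
        coded = np.where(y == lab, 1.0, -1.0)
        machines.append(fit_lssvm(X, coded, gamma, sigma2, task="classification"))
    return MulticlassLSSVM(class_labels=labels, machines=machines)


def predict_lssvm_classifier(m: MulticlassLSSVM, X: np.ndarray) -> list[str]:
    """Argmax of one-vs-rest decision values; ties go to the first label."""
    decisions = np.column_stack([predict_lssvm(mach, X) for mach in m.machines])
    return [m.class_labels[i] for i in np.argmax(decisions, axis=1)]


# ---------------------------------------------------------------------------
# Hyperparameter tuning


@dataclass(frozen=True)
class HyperparameterGrid:
    """Log-spaced search grid for (gamma, sigma2) with k-fold CV."""

    gamma_values: tuple[float, ...] = (1e-1, 1e0, 1e1, 1e2, 1e3, 1e4)
    sigma2_values: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1e0, 1e1, 1e2)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gamma_values or not self.sigma2_values:
            raise ValueError("grid value lists must be nonempty")
        if any(g <= 0 for g in self.gamma_values) or any(
            s <= 0 for s in self.sigma2_values
        ):
            raise ValueError("grid values must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _make_folds(
    n: int, n_folds: int, seed: int, y: np.ndarray | None = None
) -> list[np.ndarray]:
    """Deterministic folds; stratified by label when ``y`` is given."""
    rng = np.random.default_rng(seed)
    n_folds = min(n_folds, n)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    if y is None:
        order = rng.permutation(n)
        for pos, ix in enumerate(order):
            folds[pos % n_folds].append(int(ix))
    else:
        y = np.asarray(y)
        offset = 0
        for lab in dict.fromkeys(y.tolist()):
            members = np.flatnonzero(y == lab)
            members = members[rng.permutation(len(members))]
            for pos, ix in enumerate(members):
                folds[(offset + pos) % n_folds].append(int(ix))
            offset += len(members)
    return [np.asarray(sorted(f), dtype=int) for f in folds if len(f)]


def tune_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid,
    task: Task,
) -> tuple[float, float]:
    """Exhaustive grid search minimizing CV misclassification rate or RMSE.

    Folds are fixed once per call (deterministic given the grid seed) and
    shared by every (gamma, sigma2) candidate; classification folds are
    stratified so each fold sees every class. Ties prefer the smallest
    gamma, then the smallest sigma2.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = X.shape[0]
    if task == "classification":
        folds = _make_folds(n, grid.cv_folds, grid.seed, y=y)
        class_order = list(dict.fromkeys(y.tolist()))
    else:
        folds = _make_folds(n, grid.cv_folds, grid.seed)
        class_order = None

    best: tuple[float, float] | None = None
    best_score = np.inf
    for gamma in sorted(grid.gamma_values):
        for sigma2 in sorted(grid.sigma2_values):
            errs = []
            for fold in folds:
                mask = np.ones(n, dtype=bool)
                mask[fold] = False
                if task == "classification":
                    if len(set(y[mask].tolist())) < 2:
                        continue
                    model = fit_lssvm_classifier(
                        X[mask], y[mask], gamma, sigma2, class_order=class_order
                    )
                    pred = predict_lssvm_classifier(model, X[fold])
                    errs.append(float(np.mean(np.asarray(pred) != y[fold])))
                else:
                    model = fit_lssvm(
                        X[mask], y[mask].astype(float), gamma, sigma2, "regression"
                    )
                    resid = predict_lssvm(model, X[fold]) - y[fold].astype(float)
                    errs.append(float(np.sqrt(np.mean(resid**2))))
            score = float(np.mean(errs))
            if score < best_score - 1e-12:
                best_score = score
                best = (gamma, sigma2)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Serialization

_KINDS = {
    "lda": LDAModel,
    "mlr": MLRModel,
    "lssvm": LSSVMModel,
    "lssvm_multiclass": MulticlassLSSVM,
}


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("kind")
    if kind not in _KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    return _KINDS[kind].from_dict(d)
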