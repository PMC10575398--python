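"""Emotion-vs-rest state classifier: Gaussian-kernel SVM.

Kernel convention K(x, y) = exp(-||x - y||^2 / s^2) with s the kernel scale,
so the underlying RBF gamma is 1/s^2.  Probabilities come from Platt scaling.
Optional Bayesian hyperparameter optimization searches (kernel_scale,
box_constraint) in log space with a Gaussian-process surrogate, expected
improvement acquisition, and inner 5-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

STATE_LABELS = ("emotion", "rest")


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "gaussian"
    kernel_scale: float = 6.385
    box_constraint: float = 956.32
    multiclass: str = "one_vs_one"  # vacuous for 2 classes, kept for fidelity
    standardize: bool = False
    optimize: bool = False
    opt_iters: int = 100
    search_log10_bounds: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        if self.kernel_scale <= 0 or self.box_constraint <= 0:
            raise ValueError("kernel_scale and box_constraint must be > 0")


@dataclass(frozen=True)
class StatePrediction:
    label: str
    probability: float  # probability of the predicted label

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class EmotionDetector:
    model: SVC
    config: SvmConfig
    n_features: int
    fit_report: dict = field(default_factory=dict)


def _make_svc(kernel_scale: float, box_constraint: float, seed: int) -> SVC:
    return SVC(
        kernel="rbf",
        gamma=1.0 / kernel_scale**2,
        C=box_constraint,
        probability=True,
        random_state=seed,
    )


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, scale: float, box: float, seed: int, folds: int = 5
) -> float:
    svc = SVC(kernel="rbf", gamma=1.0 / scale**2, C=box, random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(svc, X, y, cv=cv)))


def bayes_optimize(
    X: np.ndarray,
    y: np.ndarray,
    iters: int,
    seed: int,
    log10_bounds: tuple[float, float] = (-3.0, 3.0),
    n_init: int = 8,
) -> tuple[float, float, list[dict]]:
    """GP + expected-improvement search for (kernel_scale, box_constraint)."""
    rng = np.random.default_rng(seed)
    lo, hi = log10_bounds
    pts: list[np.ndarray] = []
    vals: list[float] = []
    history: list[dict] = []

    def evaluate(p: np.ndarray) -> None:
        acc = _cv_accuracy(X, y, 10.0 ** p[0], 10.0 ** p[1], seed)
        pts.append(p)
        vals.append(acc)
        history.append({"log10_scale": p[0], "log10_box": p[1], "cv_accuracy": acc})

    for _ in range(min(n_init, iters)):
        evaluate(rng.uniform(lo, hi, size=2))
    gp = GaussianProcessRegressor(
        kernel=ConstantKernel(1.0) * Matern(length_scale=1.0, nu=2.5),
        alpha=1e-4,
        normalize_y=True,
        random_state=seed,
    )
    for _ in range(max(iters - n_init, 0)):
        gp.fit(np.vstack(pts), -np.asarray(vals))  # GP minimizes
        cand = rng.uniform(lo, hi, size=(256, 2))
        mu, sd = gp.predict(cand, return_std=True)
        best = -max(vals)
        sd = np.maximum(sd, 1e-9)
        z = (best - mu) / sd
        ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])
    j = int(np.argmax(vals))
    return 10.0 ** pts[j][0], 10.0 ** pts[j][1], history


def train_emotion_detector(
    features: np.ndarray,
    labels: Sequence[str],
    cfg: SvmConfig = SvmConfig(),
    seed: int = 0,
) -> EmotionDetector:
    """Fit the two-class (emotion/rest) Gaussian-kernel SVM.

    ``features`` must already be normalized to [0, 1] (see
    :class:`emophysio.hrv.FeatureScaler`).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = set(np.unique(y))
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if not classes <= set(STATE_LABELS):
        raise ValueError(f"labels must be in {STATE_LABELS}, got {sorted(classes)}")
    scale, box = cfg.kernel_scale, cfg.box_constraint
    report: dict = {"optimized": False}
    if cfg.optimize:
        scale, box, history = bayes_optimize(
            X, y, cfg.opt_iters, seed, cfg.search_log10_bounds
        )
        report = {
            "optimized": True,
            "kernel_scale": scale,
            "box_constraint": box,
            "history": history,
        }
    model = _make_svc(scale, box, seed)
    model.fit(X, y)
    report["n_support"] = model.n_support_.tolist()
    report["train_accuracy"] = float(model.score(X, y))
    return EmotionDetector(model=model, config=cfg, n_features=X.shape[1], fit_report=report)


def predict_state(detector: EmotionDetector, feature_row: np.ndarray) -> StatePrediction:
    row = np.asarray(feature_row, dtype=float).reshape(1, -1)
    if row.shape[1] != detector.n_features:
        raise ValueError(
            f"expected {detector.n_features} features, got {row.shape[1]}"
        )
    probs = detector.model.predict_proba(row)[0]
    j = int(np.argmax(probs))
    return StatePrediction(label=str(detector.model.classes_[j]), probability=float(probs[j]))
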