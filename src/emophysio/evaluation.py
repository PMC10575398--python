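"""Dataset assembly (arousal conversion, splits, distribution tables),
classification metrics, Monte Carlo cross-validation, and the end-to-end
pipeline orchestration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import ecg as ecg_mod
from . import eda as eda_mod
from . import hrv as hrv_mod
from .classifiers.nn import CnnTrainConfig, train_arousal_classifier
from .classifiers.svm import SvmConfig, train_emotion_detector
from .scalogram import cwt_scalogram, scalogram_to_image
from .synthetic import ProtocolSpec, SubjectSession
from .types import RRSeries, SegmentAnnotation

log = logging.getLogger(__name__)

AROUSAL_CLASSES = ("low", "mid", "high")


def arousal_to_class(sam: int) -> str:
    """9-point SAM arousal -> {low, mid, high}: 1-3, 4-6, 7-9."""
    s = int(sam)
    if not 1 <= s <= 9:
        raise ValueError(f"SAM arousal must be in 1..9, got {sam}")
    return AROUSAL_CLASSES[(s - 1) // 3]


def class_weights(labels: Sequence[str]) -> dict[str, float]:
    """w_i = N / m_i per class; every class in the label set must be present."""
    y = list(labels)
    if not y:
        raise ValueError("empty label list")
    n = len(y)
    out = {}
    for cls in dict.fromkeys(y):
        m = y.count(cls)
        out[cls] = n / m
    return out


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = truth, cols = predicted
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative K x K matrix")

    @classmethod
    def from_predictions(
        cls, truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
    ) -> "ConfusionMatrix":
        classes = tuple(classes)
        k = len(classes)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(truth, predicted, strict=True):
            counts[classes.index(t), classes.index(p)] += 1
        return cls(counts=counts, classes=classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        """TP accuracy: diagonal sum over total."""
        return float(np.trace(self.counts) / self.total)


def precision_recall(cm: ConfusionMatrix, cls: str) -> tuple[float, float]:
    """One-vs-rest precision and recall for ``cls``; 0/0 reported as NaN."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    i = cm.classes.index(cls)
    tp = cm.counts[i, i]
    fp = cm.counts[:, i].sum() - tp
    fn = cm.counts[i, :].sum() - tp
    precision = float("nan") if tp + fp == 0 else tp / (tp + fp)
    recall = float("nan") if tp + fn == 0 else tp / (tp + fn)
    return float(precision), float(recall)


def f_beta(precision: float, recall: float, beta: float = 1.0) -> float:
    """(1 + b^2) P R / (b^2 P + R); defined as 0 with a warning when P = R = 0."""
    if math.isnan(precision) or math.isnan(recall):
        return float("nan")
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision == 0 and recall == 0:
        log.warning("f_beta: precision and recall both 0; score defined as 0")
        return 0.0
    b2 = beta**2
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def monte_carlo_cv(
    labels: Sequence[str], k: int = 5, val_frac: float = 0.2, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k independent stratified random (train, validation) index splits.

    Repeated random sub-sampling, not a disjoint partition: each fold draws
    its own validation set, preserving class proportions within one
    observation per class.
    """
    if not 0.0 < val_frac < 1.0:
        raise ValueError("val_frac must be in (0, 1)")
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(k):
        val_idx: list[int] = []
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            n_val = int(round(val_frac * members.size))
            n_val = min(max(n_val, 1), members.size - 1) if members.size > 1 else 0
            val_idx.extend(rng.permutation(members)[:n_val].tolist())
        val = np.sort(np.asarray(val_idx, dtype=int))
        train = np.setdiff1d(np.arange(y.size), val)
        splits.append((train, val))
    return splits


def stratified_split(
    sam_labels: Sequence[int], train_frac: float = 0.9, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split with every 9-point SAM value in the test set.

    The test size is floor((1 - train_frac) * N).  Classes with a single
    observation relax the coverage constraint with a warning.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    y = np.asarray(sam_labels, dtype=int)
    if np.any((y < 1) | (y > 9)):
        raise ValueError("SAM labels must be in 1..9")
    n = y.size
    n_test = int(math.floor((1.0 - train_frac) * n))
    rng = np.random.default_rng(seed)
    test: list[int] = []
    for s in np.unique(y):
        members = np.flatnonzero(y == s)
        if members.size < 2:
            log.warning("stratified_split: SAM class %d has < 2 observations", s)
            if members.size < 1:
                continue
        test.append(int(rng.choice(members)))
    remaining = np.setdiff1d(np.arange(n), np.asarray(test, dtype=int))
    extra = max(n_test - len(test), 0)
    if extra:
        test.extend(rng.permutation(remaining)[:extra].tolist())
    test_arr = np.sort(np.asarray(test, dtype=int))
    train_arr = np.setdiff1d(np.arange(n), test_arr)
    return train_arr, test_arr


@dataclass
class DatasetSummary:
    """Distribution tables for an annotated cohort."""

    category_counts: dict[str, dict[str, int]]  # category -> method -> count
    rest_counts: dict[str, int]  # method pooled under "rest"
    sam_counts: dict[int, int]  # 9-point arousal distribution
    arousal_counts: dict[str, int]  # 3-class distribution
    n_subjects: int

    @property
    def n_emotion(self) -> int:
        return sum(sum(m.values()) for m in self.category_counts.values())

    @property
    def n_rest(self) -> int:
        return sum(self.rest_counts.values())

    @property
    def total(self) -> int:
        return self.n_emotion + self.n_rest


def summarize_sam_counts(sam_counts: dict[int, int]) -> dict[str, int]:
    """Aggregate a 9-point count table into the 3-class arousal totals."""
    out = {c: 0 for c in AROUSAL_CLASSES}
    for sam, count in sam_counts.items():
        out[arousal_to_class(sam)] += int(count)
    return out


def dataset_summary(cohort: Sequence[SubjectSession]) -> DatasetSummary:
    """Per-category counts by induction method, SAM and arousal distributions.

    The baseline segment is excluded from the two-class totals.
    """
    category_counts: dict[str, dict[str, int]] = {}
    rest_counts = {"after_image": 0, "after_recall": 0}
    sam_counts = {s: 0 for s in range(1, 10)}
    for session in cohort:
        prev_method = "none"
        for ann in session.annotations:
            if ann.stage in ("stimulus", "recall"):
                cat = category_counts.setdefault(ann.category, {"image": 0, "recall": 0})
                cat[ann.method] += 1
                if ann.sam is not None:
                    sam_counts[int(ann.sam)] += 1
                prev_method = ann.method
            elif ann.stage == "rest":
                key = "after_image" if prev_method == "image" else "after_recall"
                rest_counts[key] += 1
    return DatasetSummary(
        category_counts=category_counts,
        rest_counts=rest_counts,
        sam_counts=sam_counts,
        arousal_counts=summarize_sam_counts(sam_counts),
        n_subjects=len(cohort),
    )


def reduction_percent(original_total: int, selected_total: int) -> float:
    """100 * (original - selected) / original."""
    if original_total <= 0:
        raise ValueError("original_total must be > 0")
    return 100.0 * (original_total - selected_total) / original_total


@dataclass
class CvReport:
    classes: tuple[str, ...]
    fold_accuracy: list[float]
    fold_precision: dict[str, list[float]]
    fold_recall: dict[str, list[float]]
    fold_f1: dict[str, list[float]]
    confusion: ConfusionMatrix

    @staticmethod
    def _mean_sd(values: list[float]) -> tuple[float, float]:
        arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        return float(arr.mean()), float(arr.std(ddof=0))

    @property
    def mean_accuracy(self) -> float:
        return self._mean_sd(self.fold_accuracy)[0]

    def summary(self) -> dict:
        out = {
            "classes": list(self.classes),
            "accuracy": dict(zip(("mean", "sd"), self._mean_sd(self.fold_accuracy))),
            "per_class": {},
            "confusion": self.confusion.counts.tolist(),
        }
        for cls in self.classes:
            out["per_class"][cls] = {
                "precision": dict(zip(("mean", "sd"), self._mean_sd(self.fold_precision[cls]))),
                "recall": dict(zip(("mean", "sd"), self._mean_sd(self.fold_recall[cls]))),
                "f1": dict(zip(("mean", "sd"), self._mean_sd(self.fold_f1[cls]))),
            }
        return out


def _report_from_folds(
    fold_results: list[tuple[list[str], list[str]]], classes: tuple[str, ...]
) -> CvReport:
    accs, precs, recs, f1s = [], {c: [] for c in classes}, {c: [] for c in classes}, {c: [] for c in classes}
    total = np.zeros((len(classes), len(classes)), dtype=int)
    for truth, pred in fold_results:
        cm = ConfusionMatrix.from_predictions(truth, pred, classes)
        total += cm.counts
        accs.append(cm.accuracy())
        for c in classes:
            p, r = precision_recall(cm, c)
            precs[c].append(p)
            recs[c].append(r)
            f1s[c].append(f_beta(p, r))
    return CvReport(
        classes=classes,
        fold_accuracy=accs,
        fold_precision=precs,
        fold_recall=recs,
        fold_f1=f1s,
        confusion=ConfusionMatrix(total, classes),
    )


@dataclass(frozen=True)
class PipelineConfig:
    svm: SvmConfig = SvmConfig()
    cnn: CnnTrainConfig = CnnTrainConfig()
    cv_folds: int = 5
    val_frac: float = 0.2
    image_size: int = 64
    use_detected_triggers: bool = True
    seed: int = 0


@dataclass
class SegmentFeatures:
    subject: str
    segment_id: int
    annotation: SegmentAnnotation
    rr: RRSeries
    features: np.ndarray


def extract_session_features(
    session: SubjectSession,
    protocol: ProtocolSpec,
    use_detected_triggers: bool = True,
) -> tuple[list[SegmentFeatures], dict]:
    """EDA branch -> segmentation -> ECG branch -> HRV features for one session."""
    if session.ecg is None or session.scl is None:
        raise ValueError("session has no signals")
    scl = eda_mod.preprocess_scl(session.scl)
    if use_detected_triggers:
        triggers = eda_mod.detect_triggers(scl)
        # the recording starts at the baseline onset; that trigger sits on the
        # signal boundary where the second derivative is unobservable
        if triggers and triggers[0].time > scl.t0 + 1.0:
            triggers = [eda_mod.TriggerMark(scl.t0, "predicted")] + triggers
        if len(triggers) < 2:
            triggers = [
                eda_mod.TriggerMark(float(t), "ground_truth")
                for t in session.truth["trigger_times"]
            ]
    else:
        triggers = [
            eda_mod.TriggerMark(float(t), "ground_truth")
            for t in session.truth["trigger_times"]
        ]
    segments = eda_mod.triggers_to_segments(
        triggers, protocol, session_end_s=session.ecg.duration_s
    )
    ecg256 = ecg_mod.downsample(session.ecg, 256.0)
    out: list[SegmentFeatures] = []
    n_bad = 0
    for seg_id, (ann, snip) in enumerate(ecg_mod.segment_session(ecg256, segments)):
        try:
            cleaned = ecg_mod.remove_raw_outliers(snip)
            rr = ecg_mod.clean_rr(ecg_mod.detect_r_peaks(cleaned))
            if len(rr) < 4:
                raise ecg_mod.UnusableSegmentError("too few RR intervals")
            fv = hrv_mod.feature_vector(rr)
        except (ecg_mod.UnusableSegmentError, ValueError) as exc:
            log.warning("%s segment %d unusable: %s", session.subject_id, seg_id, exc)
            n_bad += 1
            continue
        out.append(
            SegmentFeatures(
                subject=session.subject_id,
                segment_id=seg_id,
                annotation=ann,
                rr=rr,
                features=fv.as_array(),
            )
        )
    manifest = {
        "subject": session.subject_id,
        "n_segments": len(segments),
        "n_usable": len(out),
        "n_unusable": n_bad,
        "usable": ecg_mod.session_usable([True] * len(out) + [False] * n_bad),
    }
    return out, manifest


def run_sessions(
    sessions: Sequence[SubjectSession],
    protocol: ProtocolSpec = ProtocolSpec(),
    config: PipelineConfig = PipelineConfig(),
    train_arousal: bool = True,
) -> dict:
    """Execute both branches and both models on in-memory sessions.

    Returns a dict with the state-model and (optionally) arousal-model
    :class:`CvReport` plus a run manifest.
    """
    all_feats: list[SegmentFeatures] = []
    manifest: dict = {"subjects": [], "seed": config.seed}
    for session in sessions:
        feats, m = extract_session_features(
            session, protocol, config.use_detected_triggers
        )
        manifest["subjects"].append(m)
        if not m["usable"]:
            log.warning("%s discarded (>20%% unusable segments)", session.subject_id)
            continue
        all_feats.extend(feats)
    state_feats = [f for f in all_feats if f.annotation.stage in ("stimulus", "recall", "rest")]
    X = np.vstack([f.features for f in state_feats])
    y_state = np.array(
        ["emotion" if f.annotation.is_emotion else "rest" for f in state_feats]
    )
    state_report = cross_validate_state(X, y_state, config)
    result = {"state_report": state_report, "manifest": manifest}
    if train_arousal:
        emo = [f for f in state_feats if f.annotation.is_emotion and f.annotation.sam]
        sessions_by_id = {s.subject_id: s for s in sessions}
        images, y_arousal = [], []
        for f in emo:
            sess = sessions_by_id[f.subject]
            ecg256 = ecg_mod.downsample(sess.ecg, 256.0)
            (_, snip), = ecg_mod.segment_session(ecg256, [f.annotation])
            sc = cwt_scalogram(snip)
            images.append(scalogram_to_image(sc, (config.image_size, config.image_size)))
            y_arousal.append(arousal_to_class(f.annotation.sam))
        if len(set(y_arousal)) == 3:
            result["arousal_report"] = cross_validate_arousal(
                np.stack(images), np.array(y_arousal), config
            )
        else:
            log.warning("arousal model skipped: not all 3 classes present")
    return result


def cross_validate_state(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig = PipelineConfig()
) -> CvReport:
    """5-fold Monte Carlo CV of the emotion/rest SVM with train-fitted scaling."""
    folds = monte_carlo_cv(y, k=config.cv_folds, val_frac=config.val_frac, seed=config.seed)
    results = []
    for train_idx, val_idx in folds:
        scaler = hrv_mod.FeatureScaler().fit(X[train_idx])
        det = train_emotion_detector(
            scaler.transform(X[train_idx]), y[train_idx], config.svm, seed=config.seed
        )
        pred = det.model.predict(scaler.transform(X[val_idx]))
        results.append((list(y[val_idx]), list(pred)))
    return _report_from_folds(results, ("emotion", "rest"))


def cross_validate_arousal(
    images: np.ndarray, y: np.ndarray, config: PipelineConfig = PipelineConfig()
) -> CvReport:
    folds = monte_carlo_cv(y, k=config.cv_folds, val_frac=config.val_frac, seed=config.seed)
    results = []
    for train_idx, val_idx in folds:
        model = train_arousal_classifier(images[train_idx], y[train_idx], config.cnn)
        probs = model.predict_proba(images[val_idx])
        pred = [model.classes[int(j)] for j in np.argmax(probs, axis=1)]
        results.append((list(y[val_idx]), pred))
    return _report_from_folds(results, AROUSAL_CLASSES)
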