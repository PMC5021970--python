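"""Biomarker classification: linear SVM scores, repeated CV, combined rule.

A linear soft-margin SVM is trained on the seven mitochondrial morphology
features (z-scored). The expected outlier fraction enters as a robust
trim-and-refit: the SVM is fitted, the ``outlier_fraction`` training points
with the worst margin violations are discarded as presumed outliers, and the
SVM is refitted on the rest. (A ν-parameterization was considered but
rejected: ν upper-bounds the fraction of margin violators, so any ν below
the actual class overlap makes the ν-SVM problem degenerate.) Generalization
is estimated by repeated (default 100×) stratified 5-fold cross-validation;
per repeat, the held-out decision scores of all folds are pooled into one
AUC.

The combined classifier joins the mitochondrial SVM score with the ganglion
volume: using the prior that 60% of ganglia come from patients, the score
threshold is the 0.6-quantile of scores and the volume threshold the
0.4-quantile of volumes, and a ganglion is called *patient* when its score is
high AND its volume low (the AND rule is the default; OR is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import MITO_FEATURES
from .stats import roc_auc

__all__ = [
    "CVResult",
    "ConfusionSummary",
    "CombinedClassifier",
    "train_linear_svm",
    "repeated_cv_auc",
    "combined_classify",
    "evaluate_confusion",
]


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def evaluate_confusion(predictions: np.ndarray, truth: np.ndarray) -> ConfusionSummary:
    """Confusion counts of binary predictions against binary truth."""
    p = np.asarray(predictions, bool)
    t = np.asarray(truth, bool)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truth must be non-empty and congruent")
    return ConfusionSummary(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def _positive_scores(model: SVC, X: np.ndarray, positive_label) -> np.ndarray:
    """Decision scores oriented so higher = more like ``positive_label``."""
    scores = model.decision_function(X)
    # sklearn's decision_function is positive towards classes_[1]
    return scores if model.classes_[1] == positive_label else -scores


def _fit_trimmed_svm(Z: np.ndarray, y: np.ndarray, outlier_fraction: float, C: float) -> SVC:
    """Linear SVM with robust trimming of the assumed outlier fraction.

    Fits once, discards the ``floor(outlier_fraction * n)`` training points
    with the most negative signed margins (the presumed outliers), and refits
    on the remainder. Deterministic given the data.
    """
    svm = SVC(kernel="linear", C=C)
    svm.fit(Z, y)
    n_drop = int(outlier_fraction * len(y))
    if n_drop > 0:
        sign = np.where(y == svm.classes_[1], 1.0, -1.0)
        margins = sign * svm.decision_function(Z)
        keep = np.argsort(margins, kind="stable")[n_drop:]
        if np.unique(y[keep]).size == 2:
            svm = SVC(kernel="linear", C=C).fit(Z[keep], y[keep])
    return svm


def train_linear_svm(
    features: np.ndarray,
    labels: np.ndarray,
    outlier_fraction: float = 0.01,
    positive_label="patient",
    expect_n_features: int | None = len(MITO_FEATURES),
    C: float = 1.0,
) -> tuple[dict, np.ndarray]:
    """Train a robust linear SVM on z-scored features.

    Returns ``(model_bundle, training decision scores)`` with scores oriented
    so that higher means more patient-like. ``model_bundle`` carries the
    fitted scaler and SVM plus a ``score(X)`` callable.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if expect_n_features is not None and X.shape[1] != expect_n_features:
        raise ValueError(
            f"expected {expect_n_features} feature columns, got {X.shape[1]}"
            " (pass expect_n_features=None to override)"
        )
    if np.unique(y).size < 2:
        raise ValueError("need both classes to train")
    scaler = StandardScaler().fit(X)
    svm = _fit_trimmed_svm(scaler.transform(X), y, outlier_fraction, C)

    def score(Xnew: np.ndarray) -> np.ndarray:
        return _positive_scores(svm, scaler.transform(np.asarray(Xnew, float)), positive_label)

    bundle = {"scaler": scaler, "svm": svm, "score": score, "positive_label": positive_label}
    return bundle, score(X)


@dataclass
class CVResult:
    repeat_aucs: np.ndarray
    pooled_scores: np.ndarray  # (n_repeats, n_samples) held-out scores
    labels: np.ndarray
    n_repeats: int
    k: int
    seed: int | None

    @property
    def mean_auc(self) -> float:
        return float(self.repeat_aucs.mean())


def repeated_cv_auc(
    features: np.ndarray,
    labels: np.ndarray,
    n_repeats: int = 100,
    k: int = 5,
    seed: int | None = None,
    outlier_fraction: float = 0.01,
    positive_label="patient",
    C: float = 1.0,
) -> CVResult:
    """Repeated stratified k-fold CV of the linear ν-SVM, AUC per repeat.

    Every repeat draws a fresh stratified partition; z-scoring is fit on the
    training folds only. The held-out decision scores of the k folds are
    pooled into one ROC AUC per repeat.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < k:
        raise ValueError("need two classes with at least k members each")
    rng = np.random.SeedSequence(seed)
    fold_seeds = rng.generate_state(n_repeats) % (2**31)
    aucs = np.empty(n_repeats)
    pooled = np.empty((n_repeats, len(y)))
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(fold_seeds[r]))
        scores = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            scaler = StandardScaler().fit(X[train_idx])
            svm = _fit_trimmed_svm(
                scaler.transform(X[train_idx]), y[train_idx], outlier_fraction, C
            )
            scores[test_idx] = _positive_scores(
                svm, scaler.transform(X[test_idx]), positive_label
            )
        pooled[r] = scores
        aucs[r] = roc_auc(scores, y, positive_label=positive_label).auc
    return CVResult(aucs, pooled, y, n_repeats, k, seed)


@dataclass
class CombinedClassifier:
    """Two-threshold rule joining SVM score (high in patients) and ganglion
    volume (low in patients)."""

    score_threshold: float
    volume_threshold: float
    q_score: float = 0.6
    q_volume: float = 0.4
    rule: str = "AND"

    def predict(self, scores: np.ndarray, volumes: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, float) >= self.score_threshold
        v = np.asarray(volumes, float) <= self.volume_threshold
        return (s & v) if self.rule == "AND" else (s | v)


def combined_classify(
    svm_scores: np.ndarray,
    ganglion_volumes: np.ndarray,
    truth: np.ndarray,
    q_score: float = 0.6,
    q_volume: float = 0.4,
    rule: str = "AND",
) -> tuple[CombinedClassifier, np.ndarray, ConfusionSummary]:
    """Quantile-threshold combined classifier and its confusion summary.

    Thresholds are empirical quantiles (linear interpolation between order
    statistics) of the provided scores and volumes; the quantiles encode the
    prior class mix (default: 60% patients). Predict patient iff
    ``score >= q_score-quantile`` RULE ``volume <= q_volume-quantile``.
    """
    s = np.asarray(svm_scores, float)
    v = np.asarray(ganglion_volumes, float)
    t = np.asarray(truth, bool)
    if not (len(s) == len(v) == len(t)):
        raise ValueError("scores, volumes and truth must have equal length")
    if not (np.isfinite(s).all() and np.isfinite(v).all()):
        raise ValueError("non-finite scores or volumes")
    if np.unique(s).size < 2:
        raise ValueError("degenerate input: all SVM scores identical")
    if np.unique(v).size < 2:
        raise ValueError("degenerate input: all ganglion volumes identical")
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    if not (0 < q_score < 1 and 0 < q_volume < 1):
        raise ValueError("quantiles must lie in (0, 1)")
    clf = CombinedClassifier(
        score_threshold=float(np.quantile(s, q_score)),
        volume_threshold=float(np.quantile(v, q_volume)),
        q_score=q_score,
        q_volume=q_volume,
        rule=rule,
    )
    predictions = clf.predict(s, v)
    return clf, predictions, evaluate_confusion(predictions, t)
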