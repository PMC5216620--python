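"""Older-vs-younger linear SVM classification with LOOCV and ROC/AUC.

The positive class is "older"; sensitivity is older-recall and specificity
younger-recall. AUC is the Mann-Whitney U statistic normalized by
n_pos * n_neg (ties count one half), which equals the trapezoidal integral
of the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

from .errors import ClassSizeError, InsufficientDataError
from .types import OLDER

POSITIVE_LABEL = OLDER


@dataclass
class ClassificationResult:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float]]
    per_subject_scores: np.ndarray
    predicted_labels: list[str] = field(default_factory=list)
    p_perm: float | None = None
    n_perm: int = 0

    def to_jsonable(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "per_subject_scores": [float(s) for s in self.per_subject_scores],
            "predicted_labels": self.predicted_labels,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
        }


def roc_auc(scores, labels, positive_label: str = POSITIVE_LABEL):
    """(AUC, ROC points) from decision scores; higher score = more positive."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassSizeError("both classes must be present for ROC/AUC")
    ranks = rankdata(scores)  # average ranks -> ties contribute 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[order[j]] == scores[order[i]]:
            if pos[order[j]]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return auc, points


def _loocv_scores(X, labels, C, positive_label):
    s = X.shape[0]
    scores = np.empty(s)
    preds = []
    idx = np.arange(s)
    for i in range(s):
        tr = idx != i
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[tr] - mu) / sd, labels[tr])
        xs = ((X[i] - mu) / sd)[None, :]
        score = float(clf.decision_function(xs)[0])
        if clf.classes_[1] != positive_label:
            score = -score
        scores[i] = score
        preds.append(str(clf.predict(xs)[0]))
    return scores, preds


def svm_loocv_classify(
    X: np.ndarray,
    labels,
    C: float = 1.0,
    n_perm: int = 0,
    rng_seed: int | None = None,
    positive_label: str = POSITIVE_LABEL,
) -> ClassificationResult:
    """Leave-one-out linear SVM with training-fold feature z-scoring."""
    X = np.asarray(X, float)
    labels = np.asarray([str(l) for l in labels])
    if X.shape[0] != len(labels):
        raise ValueError("X rows must match labels")
    if X.shape[0] < 6:
        raise InsufficientDataError("need at least 6 subjects")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ClassSizeError("exactly two classes required")
    if counts.min() < 2:
        raise ClassSizeError("each class needs at least 2 members")
    scores, preds = _loocv_scores(X, labels, C, positive_label)
    preds = np.asarray(preds)
    pos = labels == positive_label
    accuracy = float((preds == labels).mean())
    sensitivity = float((preds[pos] == positive_label).mean())
    specificity = float((preds[~pos] != positive_label).mean())
    auc, points = roc_auc(scores, labels, positive_label)
    result = ClassificationResult(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        auc=auc, roc_points=points, per_subject_scores=scores,
        predicted_labels=list(preds), n_perm=n_perm,
    )
    if n_perm > 0:
        rng = np.random.default_rng(rng_seed)
        exceed = 0
        for _ in range(n_perm):
            lp = rng.permutation(labels)
            sp, pp = _loocv_scores(X, lp, C, positive_label)
            if (np.asarray(pp) == lp).mean() >= accuracy:
                exceed += 1
        result.p_perm = (exceed + 1) / (n_perm + 1)
    return result
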