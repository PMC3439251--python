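"""ROC/AUC, confusion-matrix metrics, repeated stratified cross-validation
and the nearest-neighbour comparison baseline.

The reported protocol is repeated stratified k-fold CV: per repeat the
held-out scores of all folds are pooled, the AUC is computed on the pool,
and the decision threshold is the one maximizing the F-score on the pooled
scores; sensitivity, specificity and MCC are reported at that threshold.
Means and standard deviations are taken across repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

POSITIVE = "stable"
NEGATIVE = "unstable"


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve (rank / Mann-Whitney form, ties half-credit)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes required to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels):
    """(fpr, tpr) pairs of the empirical ROC curve."""
    fpr, tpr, _ = roc_curve(np.asarray(labels, dtype=int), np.asarray(scores))
    return np.column_stack([fpr, tpr])


def threshold_metrics(counts: ConfusionCounts) -> dict:
    """Precision, recall/sensitivity, F-score, specificity and MCC.

    A metric whose denominator is zero is reported as 0.0 and listed in
    the returned ``undefined`` set rather than raising.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f_score = ratio(2 * precision * recall, precision + recall, "f_score")
    specificity = ratio(tn, tn + fp, "specificity")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")
    return {
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "f_score": f_score,
        "specificity": specificity,
        "mcc": mcc,
        "undefined": undefined,
    }


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def max_f_threshold(scores, labels) -> tuple[float, ConfusionCounts]:
    """Threshold (from the observed scores) maximizing the F-score.

    A score >= threshold predicts positive; ties on F resolve to the
    lowest candidate threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes required")
    best_t, best_f, best_c = None, -1.0, None
    for t in np.unique(scores):
        counts = confusion_at(scores, labels, t)
        f = threshold_metrics(counts)["f_score"]
        if f > best_f + 1e-15:
            best_t, best_f, best_c = float(t), f, counts
    return best_t, best_c


@dataclass
class CvReport:
    folds: int
    repeats: int
    per_repeat: list[dict] = field(default_factory=list)
    #: pooled held-out scores and labels per repeat (for ROC dumps)
    pooled: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def aggregate(self) -> dict:
        """metric -> {mean, sd} across repeats (population sd, ddof=0)."""
        out = {}
        for metric in ("auc", "f_score", "mcc", "sensitivity", "specificity"):
            vals = np.array([r[metric] for r in self.per_repeat])
            out[metric] = {"mean": float(vals.mean()), "sd": float(vals.std())}
        return out


ModelBuilder = Callable[[list, list, int], Callable[[list], np.ndarray]]


def cross_validate(
    model_builder: ModelBuilder,
    items: Sequence,
    labels: Sequence[str],
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> CvReport:
    """Repeated stratified k-fold cross-validation.

    ``model_builder(train_items, train_labels, seed)`` must return a
    scoring callable mapping held-out items to scores; all fitting
    (including any internal calibration split or background estimation)
    must happen inside the builder so nothing leaks across the fold
    boundary. Repeat ``r`` uses ``seed + r`` for both the fold assignment
    and the builder.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    items = list(items)
    labels = list(labels)
    y = np.array([1 if l == POSITIVE else 0 for l in labels])
    report = CvReport(folds=folds, repeats=repeats)
    for r in range(repeats):
        rep_seed = seed + r
        splits = None
        for attempt in range(10):
            kf = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=rep_seed + 1000 * attempt
            )
            candidate = list(kf.split(np.zeros(len(items)), y))
            if all(len(set(y[tr])) == 2 for tr, _ in candidate):
                splits = candidate
                break
        if splits is None:
            raise ValueError("could not build folds with both classes present")
        pooled_scores = np.empty(len(items))
        for train_idx, test_idx in splits:
            scorer = model_builder(
                [items[i] for i in train_idx],
                [labels[i] for i in train_idx],
                rep_seed,
            )
            pooled_scores[test_idx] = np.asarray(scorer([items[i] for i in test_idx]))
        report.pooled.append((pooled_scores.copy(), y.astype(bool)))
        auc = roc_auc(pooled_scores, y.astype(bool))
        threshold, counts = max_f_threshold(pooled_scores, y.astype(bool))
        metrics = threshold_metrics(counts)
        report.per_repeat.append(
            {
                "auc": auc,
                "f_score": metrics["f_score"],
                "mcc": metrics["mcc"],
                "sensitivity": metrics["sensitivity"],
                "specificity": metrics["specificity"],
                "threshold": threshold,
            }
        )
    return report


# ---------------------------------------------------------------------------
# Nearest-neighbour comparison baseline


@dataclass
class NnBaseline:
    """Training matrix + labels scored by 1-cosine distance margins."""

    X: np.ndarray
    labels: np.ndarray  # bool, True = positive class

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (self.labels.any() and (~self.labels).any()):
            raise ValueError("training set must contain both classes")
        if np.any(np.linalg.norm(self.X, axis=1) == 0):
            raise ValueError("zero-norm training vector")


def nn_score(baseline: NnBaseline, query: np.ndarray) -> float:
    """Nearest-neighbour margin ``D- - D+`` under 1-cosine distance.

    ``D-`` (``D+``) is the minimum distance from the query to any negative
    (positive) training vector, so larger scores mean "closer to the
    positive class".
    """
    query = np.asarray(query, dtype=float).reshape(1, -1)
    if np.linalg.norm(query) == 0:
        raise ValueError("zero-norm query vector")
    dists = cdist(query, baseline.X, metric="cosine").ravel()
    d_neg = float(dists[~baseline.labels].min())
    d_pos = float(dists[baseline.labels].min())
    return d_neg - d_pos
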