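"""Diagnostic performance statistics and the repeated-split protocol.

For a binary screening test the three headline rates are

    sensitivity  SEA = TP / (TP + FN)   (diseased cases detected)
    specificity  SPA = TN / (TN + FP)   (healthy cases cleared)
    overall      OC  = (TP + TN) / N    (all cases classified correctly)

together with the ROC curve (true-positive rate against false-positive rate
across decision thresholds) and its area AUC, which equals the probability
that a random positive case outscores a random negative one, ties counted
half.

`run_protocol` runs a repeated-holdout or k-fold evaluation: every repeat
fits the supplied pipeline on the training rows only (standardization and any
hyperparameter search included), scores the held-out rows, and emits an
EvalReport; the aggregate is the arithmetic mean over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import (
    GroupKFold,
    GroupShuffleSplit,
    ShuffleSplit,
    StratifiedKFold,
    StratifiedShuffleSplit,
)

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "SplitPlan",
    "UndefinedStatisticError",
    "confusion",
    "sensitivity",
    "specificity",
    "overall",
    "roc_curve",
    "auc",
    "evaluate_scores",
    "run_protocol",
]


class UndefinedStatisticError(ZeroDivisionError):
    """A rate whose denominator is zero is undefined, not silently 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    overall: float
    roc_points: np.ndarray  # ordered (FPR, TPR) pairs
    auc: float


def confusion(true_labels, predicted, positive_class) -> ConfusionCounts:
    """Standard 2x2 tally with the declared positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors must have equal length")
    classes = set(np.unique(t).tolist()) | {positive_class}
    if len(classes) > 2:
        raise ValueError(f"more than two classes present: {sorted(map(str, classes))}")
    unseen = set(np.unique(p).tolist()) - classes
    if unseen:
        raise ValueError(f"predicted labels contain unseen values: {sorted(map(str, unseen))}")
    tpos = t == positive_class
    ppos = p == positive_class
    return ConfusionCounts(
        TP=int(np.sum(tpos & ppos)),
        TN=int(np.sum(~tpos & ~ppos)),
        FP=int(np.sum(~tpos & ppos)),
        FN=int(np.sum(tpos & ~ppos)),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN): fraction of diseased cases classified as diseased."""
    denom = counts.TP + counts.FN
    if denom == 0:
        raise UndefinedStatisticError("sensitivity undefined: no positive cases")
    return counts.TP / denom


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP): fraction of healthy cases classified as healthy."""
    denom = counts.TN + counts.FP
    if denom == 0:
        raise UndefinedStatisticError("specificity undefined: no negative cases")
    return counts.TN / denom


def overall(counts: ConfusionCounts) -> float:
    """(TP + TN) / total: overall classification correct ratio."""
    if counts.total == 0:
        raise UndefinedStatisticError("overall accuracy undefined: no cases")
    return (counts.TP + counts.TN) / counts.total


def roc_curve(true_labels, scores, positive_class) -> np.ndarray:
    """ROC points swept over the distinct score values, highest first.

    A case is predicted positive iff its score is >= the threshold; tied
    scores collapse to a single point.  The returned array always begins at
    (0, 0) and ends at (1, 1), with both coordinates non-decreasing.
    """
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    pos = t == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present in the truth labels")
    points = [(0.0, 0.0)]
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        tpr = np.sum(pred & pos) / n_pos
        fpr = np.sum(pred & ~pos) / n_neg
        points.append((float(fpr), float(tpr)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.array(points)


def auc(roc_points) -> float:
    """Trapezoidal area under an ordered (FPR, TPR) list."""
    pts = np.asarray(roc_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need an ordered list of at least 2 (FPR, TPR) points")
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate_scores(true_labels, scores, positive_class, negative_class=None) -> EvalReport:
    """Full report from decision scores: threshold-0 confusion plus ROC/AUC."""
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if negative_class is None:
        rest = [c for c in np.unique(t) if c != positive_class]
        if len(rest) != 1:
            raise ValueError("cannot infer the negative class")
        negative_class = rest[0]
    predicted = np.where(s >= 0, positive_class, negative_class)
    counts = confusion(t, predicted, positive_class)
    pts = roc_curve(t, s, positive_class)
    return EvalReport(
        counts=counts,
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        overall=overall(counts),
        roc_points=pts,
        auc=auc(pts),
    )


@dataclass(frozen=True)
class SplitPlan:
    """How to split the data: repeated stratified holdout or k-fold.

    ``repeats`` is the number of independent holdout draws, or the number of
    times the whole k-fold cycle is rerun (every fold yields one report).
    ``group_aware`` keeps all recordings of one subject on the same side of
    every split (requires groups passed to :func:`run_protocol`).
    """

    scheme: str = "repeated_holdout"
    train_fraction: float = 2.0 / 3.0
    k: int = 3
    repeats: int = 3
    stratified: bool = True
    group_aware: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("repeated_holdout", "k_fold"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "repeated_holdout" and not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.scheme == "k_fold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _splits(plan: SplitPlan, X, y, groups):
    if plan.group_aware and groups is None:
        raise ValueError("group-aware plan requires groups")
    if plan.scheme == "repeated_holdout":
        if plan.group_aware:
            splitter = GroupShuffleSplit(
                n_splits=plan.repeats, train_size=plan.train_fraction, random_state=plan.seed
            )
        elif plan.stratified:
            splitter = StratifiedShuffleSplit(
                n_splits=plan.repeats, train_size=plan.train_fraction, random_state=plan.seed
            )
        else:
            splitter = ShuffleSplit(
                n_splits=plan.repeats, train_size=plan.train_fraction, random_state=plan.seed
            )
        yield from splitter.split(X, y, groups)
        return
    for rep in range(plan.repeats):
        if plan.group_aware:
            # GroupKFold is deterministic; repeats > 1 would duplicate folds
            splitter = GroupKFold(n_splits=plan.k)
        else:
            splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed + rep)
        yield from splitter.split(X, y, groups)


def run_protocol(dataset, plan: SplitPlan, pipeline, groups=None):
    """Fit-and-evaluate over every split of the plan.

    ``pipeline`` is a factory ``(train_X, train_labels) -> model`` whose
    product exposes ``decision_scores(X)``; everything learned (including
    standardization statistics and any hyperparameter search) must come from
    the training rows it receives.

    Returns ``(reports, aggregate)`` where aggregate holds the arithmetic
    means of sensitivity, specificity, overall accuracy and AUC.
    """
    X = dataset.features
    y = dataset.labels
    if groups is None and plan.group_aware and dataset.ids is not None:
        groups = dataset.ids
    reports: list[EvalReport] = []
    for rep, (train_idx, test_idx) in enumerate(_splits(plan, X, y, groups)):
        y_train = y[train_idx]
        if np.unique(y_train).shape[0] < 2:
            raise ValueError(f"repeat {rep}: training split contains a single class")
        model = pipeline(X[train_idx], y_train)
        scores = model.decision_scores(X[test_idx])
        reports.append(evaluate_scores(y[test_idx], scores, dataset.positive_class))
    aggregate = {
        "sensitivity": float(np.mean([r.sensitivity for r in reports])),
        "specificity": float(np.mean([r.specificity for r in reports])),
        "overall": float(np.mean([r.overall for r in reports])),
        "auc": float(np.mean([r.auc for r in reports])),
    }
    return reports, aggregate
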