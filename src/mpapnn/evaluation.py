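"""Confusion-matrix metrics and resampling protocols.

Covers the two evaluation designs used in the benchmark study: a single
stratified 70/30 hold-out split, and stratified 5-fold cross-validation
repeated 30 times with sequential seeds 1..30.  Metrics are reported on the
percent scale (AUC in [0, 1]) to match the conventions of published
comparison tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "SplitPlan",
    "KFoldPlan",
    "confusion",
    "accuracy_from_confusion",
    "auc_score",
    "metric_report",
    "stratified_holdout",
    "repeated_stratified_kfold",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary TP/FP/TN/FN counts with a declared positive label."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Accuracy/precision/recall/F1 on the percent scale, AUC in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    averaging: Literal["positive_class", "macro"] = "positive_class"
    confusion: Optional[ConfusionMatrix] = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def _default_positive(classes: Sequence) -> object:
    """The numerically/lexicographically larger label (commonly 1)."""
    return sorted(classes)[-1]


def confusion(y_true, y_pred, positive_label=None) -> ConfusionMatrix:
    """Standard binary confusion counts for the declared positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if classes.size > 2:
        raise ValueError(
            "confusion counts are binary; use metric_report with averaging='macro' "
            "for multiclass problems"
        )
    if positive_label is None:
        positive_label = _default_positive(classes.tolist())
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def accuracy_from_confusion(cm: ConfusionMatrix) -> float:
    """Accuracy = (TP+TN)/(TP+TN+FP+FN), in percent, full precision."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"undefined {what} (zero denominator) reported as 0", stacklevel=3)
        return 0.0
    return num / den


def auc_score(y_true, scores, positive_label) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Midranks handle tied scores; equals the probability a random positive
    outscores a random negative (ties counting one half).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class present; reported as 0.5", stacklevel=2)
        return 0.5
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def metric_report(
    y_true,
    y_pred,
    scores=None,
    positive_label=None,
    averaging: Literal["positive_class", "macro"] = "positive_class",
) -> MetricReport:
    """Accuracy, precision, recall, F1 (percent) and AUC for one run.

    ``scores`` are per-instance positive-class scores for binary problems or
    an m×C score matrix (class-set column order) for macro averaging.  F1 is
    the harmonic mean of the reported precision and recall per averaging
    mode; macro mode averages one-vs-rest values over classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    accuracy = 100.0 * float(np.mean(y_true == y_pred))

    if averaging == "positive_class":
        if len(classes) > 2:
            raise ValueError("positive_class averaging requires binary labels")
        cm = confusion(y_true, y_pred, positive_label)
        if positive_label is None:
            positive_label = _default_positive(classes)
        precision = 100.0 * _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")
        recall = 100.0 * _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")
        f1 = _safe_ratio(2 * precision * recall, precision + recall, "F1")
        if scores is not None:
            scores = np.asarray(scores, dtype=float)
            if scores.ndim == 2:
                scores = scores[:, classes.index(positive_label)]
            auc = auc_score(y_true, scores, positive_label)
        else:
            auc = float("nan")
        return MetricReport(accuracy, precision, recall, f1, auc, averaging, cm)

    # macro: one-vs-rest per class, averaged
    precisions, recalls, f1s, aucs = [], [], [], []
    scores = None if scores is None else np.asarray(scores, dtype=float)
    for j, cls in enumerate(classes):
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        p = 100.0 * _safe_ratio(tp, tp + fp, f"precision[{cls}]")
        r = 100.0 * _safe_ratio(tp, tp + fn, f"recall[{cls}]")
        precisions.append(p)
        recalls.append(r)
        f1s.append(_safe_ratio(2 * p * r, p + r, f"F1[{cls}]"))
        if scores is not None:
            col = scores[:, j] if scores.ndim == 2 else scores
            aucs.append(auc_score((y_true == cls).astype(int), col, 1))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    return MetricReport(
        accuracy,
        float(np.mean(precisions)),
        float(np.mean(recalls)),
        float(np.mean(f1s)),
        auc,
        "macro",
        None,
    )


@dataclass
class SplitPlan:
    """One stratified train/test partition of indices 0..n-1."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    fraction: float


@dataclass
class KFoldPlan:
    """Repeated stratified k-fold assignments.

    ``fold_assignments[r][i]`` is the test-fold id of instance i in
    repetition r (generated from ``seeds[r]``).
    """

    k: int
    repetitions: int
    seeds: list
    fold_assignments: list = field(default_factory=list)

    def test_indices(self, repetition: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments[repetition] == fold)

    def train_indices(self, repetition: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments[repetition] != fold)


def _largest_remainder_counts(class_sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Per-class train counts: floor the exact shares, then hand the leftover
    seats to the largest fractional remainders (ties to earlier classes)."""
    exact = class_sizes * fraction
    base = np.floor(exact).astype(int)
    target_total = int(round(class_sizes.sum() * fraction))
    leftover = target_total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for idx in order[:leftover]:
        base[idx] += 1
    # every class keeps at least one instance on each side
    base = np.clip(base, 1, class_sizes - 1)
    return base


def stratified_holdout(dataset, fraction: float = 0.7, seed: int = 42) -> SplitPlan:
    """Stratified hold-out split (default 70% train / 30% test).

    Per class the membership is shuffled by a generator seeded from ``seed``
    and the first k_c indices go to training, with k_c chosen by
    largest-remainder rounding of the global fraction.
    """
    labels = np.asarray(dataset.labels)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    classes = sorted(np.unique(labels).tolist())
    sizes = np.array([(labels == c).sum() for c in classes])
    if (sizes < 2).any():
        raise ValueError("every class needs at least 2 members for a stratified split")
    counts = _largest_remainder_counts(sizes, fraction)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, k in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        train.append(idx[:k])
        test.append(idx[k:])
    return SplitPlan(
        train_indices=np.sort(np.concatenate(train)),
        test_indices=np.sort(np.concatenate(test)),
        seed=seed,
        fraction=fraction,
    )


def repeated_stratified_kfold(
    dataset,
    k: int = 5,
    repetitions: int = 30,
    seeds: Optional[Sequence[int]] = None,
) -> KFoldPlan:
    """Stratified k-fold assignments, one per repetition seed (default 1..30).

    Within each repetition every class is shuffled and dealt round-robin into
    the k folds (fold order itself shuffled per class so leftover instances
    do not pile onto the same folds), so per-class fold sizes differ by at
    most one and the test folds partition all indices.
    """
    labels = np.asarray(dataset.labels)
    if seeds is None:
        seeds = list(range(1, repetitions + 1))
    seeds = list(seeds)
    if len(seeds) != repetitions:
        raise ValueError("need one seed per repetition")
    classes = sorted(np.unique(labels).tolist())
    sizes = np.array([(labels == c).sum() for c in classes])
    if (sizes < k).any():
        raise ValueError(f"every class needs at least k={k} members")
    plan = KFoldPlan(k=k, repetitions=repetitions, seeds=seeds)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        assignment = np.empty(labels.size, dtype=int)
        for cls in classes:
            idx = rng.permutation(np.flatnonzero(labels == cls))
            fold_order = rng.permutation(k)
            assignment[idx] = fold_order[np.arange(idx.size) % k]
        plan.fold_assignments.append(assignment)
    return plan
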