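"""Evaluation: confusion-matrix metrics, stratified splits, ROC.

Metrics follow the usual binary-classification identities — accuracy
(TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP) and the harmonic-mean F1 — computed with exact
rational arithmetic on integer counts before float conversion.  The
training fitness maximised by the metaheuristic is the arithmetic mean
of accuracy, sensitivity and specificity on a held-out validation
split, which is why every split here is stratified: a validation slice
missing a class would leave sensitivity or specificity undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "EvalMetrics",
    "SplitSpec",
    "compute_metrics",
    "classification_fitness",
    "split_train_test",
    "kfold_splits",
    "roc_curve",
]


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and the derived fraction-valued metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class SplitSpec:
    """Either a training-percentage split or stratified k folds."""

    mode: str = "train_pct"  # "train_pct" | "kfold"
    train_pct: int = 90
    k: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("train_pct", "kfold"):
            raise ValueError("mode must be 'train_pct' or 'kfold'")
        if self.mode == "train_pct" and not 1 <= self.train_pct <= 99:
            raise ValueError("train_pct must lie in [1, 99]")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")


def compute_metrics(labels: np.ndarray, predictions: np.ndarray) -> EvalMetrics:
    """Exact confusion-count metrics for binary labels.

    Undefined ratios (an empty actual or predicted class) are reported
    as 0.0 rather than raising, so degenerate predictors still score.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    predictions = np.asarray(predictions, dtype=np.int64).ravel()
    if labels.size == 0:
        raise ValueError("cannot compute metrics on empty input")
    if labels.size != predictions.size:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))

    def ratio(num: int, den: int) -> Fraction:
        return Fraction(num, den) if den else Fraction(0)

    accuracy = Fraction(tp + tn, tp + tn + fp + fn)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    recall = sensitivity
    f1_den = precision + recall
    f1 = 2 * precision * recall / f1_den if f1_den else Fraction(0)
    return EvalMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
    )


def classification_fitness(labels: np.ndarray, predictions: np.ndarray) -> float:
    """(accuracy + sensitivity + specificity) / 3 on a validation split.

    Raises if either class is absent — the quantity is undefined then,
    and the caller should use a stratified split.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "validation split contains a single class; sensitivity/specificity "
            "are undefined — use a stratified split"
        )
    m = compute_metrics(labels, predictions)
    return (m.accuracy + m.sensitivity + m.specificity) / 3.0


def _stratified_permutation(labels: np.ndarray, rng: np.random.Generator) -> dict[int, np.ndarray]:
    return {
        int(c): rng.permutation(np.flatnonzero(labels == c)) for c in np.unique(labels)
    }


def split_train_test(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (train, validation, test) index arrays.

    train_pct percent of each class goes to train+validation and the
    rest to test; ``validation_fraction`` of the training part of each
    class is carved out for the training fitness.  Deterministic under
    the spec seed.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 segments of each class to split; generate more data")
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    for cls, order in _stratified_permutation(labels, rng).items():
        n_train_total = int(round(len(order) * spec.train_pct / 100.0))
        n_train_total = min(max(n_train_total, 2), len(order) - 1)
        n_val = max(1, int(round(n_train_total * spec.validation_fraction)))
        train_part = order[:n_train_total]
        val_idx.append(train_part[:n_val])
        train_idx.append(train_part[n_val:])
        test_idx.append(order[n_train_total:])
    train = np.sort(np.concatenate(train_idx))
    val = np.sort(np.concatenate(val_idx))
    test = np.sort(np.concatenate(test_idx))
    for name, part in (("train", train), ("validation", val), ("test", test)):
        if len(np.unique(labels[part])) < 2:
            raise ValueError(f"{name} part lost a class; generate more data")
    return train, val, test


def kfold_splits(labels: np.ndarray, spec: SplitSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k disjoint, exhaustive (train_idx, test_idx) pairs."""
    labels = np.asarray(labels, dtype=np.int64).ravel()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < spec.k:
        raise ValueError(f"need >= k={spec.k} segments per class; generate more data")
    rng = np.random.default_rng(spec.seed)
    folds: list[list[np.ndarray]] = [[] for _ in range(spec.k)]
    for _, order in _stratified_permutation(labels, rng).items():
        for i, chunk in enumerate(np.array_split(order, spec.k)):
            folds[i].append(chunk)
    fold_idx = [np.sort(np.concatenate(parts)) for parts in folds]
    all_idx = np.arange(labels.size)
    return [
        (np.setdiff1d(all_idx, test, assume_unique=False), test) for test in fold_idx
    ]


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoidal AUC from class-1 probabilities.

    Thresholds sweep the unique scores from high to low; the curve is
    anchored at (0, 0) and (1, 1).  Returns (fpr, tpr, auc).
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined for single-class labels")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep the last index of each tied-score block
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), scores.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
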