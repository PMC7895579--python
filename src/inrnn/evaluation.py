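"""Confusion-matrix metrics, one-vs-rest ROC/AUC and cross-validation.

Conventions
-----------
The confusion matrix is laid out rows = actual class, columns = predicted
class. Overall accuracy is the micro form, 100·trace/total; the macro
average of per-class one-vs-rest accuracies is exposed separately as
``macro_ovr_accuracy``. Weighted precision/recall/F1 average the
per-class values with the actual class supports as weights, which makes
support-weighted recall algebraically identical to overall accuracy.
A class that is never predicted (or never occurs) gets precision (or
recall) 0 with a warning, matching common tooling.

One-vs-rest AUC uses the rank statistic: the probability that a random
positive instance outscores a random negative one, ties counted half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .data_io import (ConfigurationError, DataError, LabeledDataset,
                      apply_minmax, fit_minmax, stratified_kfold)
from .neutrosophic import DualModel, fit_dual, predict
from .rough_core import RNNConfig

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "overall_accuracy",
    "macro_ovr_accuracy",
    "per_class_prf",
    "weighted_prf",
    "roc_auc",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass
class ConfusionMatrix:
    """k×k counts of actual (rows) vs predicted (columns) classes."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ConfigurationError("counts must be k×k over class_order")
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def actual_counts(self) -> np.ndarray:
        """Per-class supports (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def predicted_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class index i."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn

    def pretty(self) -> str:
        """Render with margins: rows actual, columns predicted."""
        names = self.class_order
        width = max(10, *(len(n) for n in names))
        head = " " * width + "".join(f"{n:>{width}}" for n in names)
        head += f"{'Total':>{width}}"
        lines = [head]
        for i, n in enumerate(names):
            cells = "".join(f"{self.counts[i, j]:>{width}}"
                            for j in range(len(names)))
            lines.append(f"{n:<{width}}{cells}{self.actual_counts[i]:>{width}}")
        foot = f"{'Total':<{width}}" + "".join(
            f"{c:>{width}}" for c in self.predicted_counts)
        foot += f"{self.total:>{width}}"
        lines.append(foot)
        return "\n".join(lines)


@dataclass
class MetricsReport:
    """All performance figures for one evaluated split.

    Percentages are on the 0–100 scale, per-class precision/recall/F1
    are fractions in [0, 1], AUC is in [0, 1].
    """

    accuracy: float
    per_class: dict[str, dict[str, float]]
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    weighted_f1_harmonic: float
    auc: dict[str, float] = field(default_factory=dict)
    confusion: ConfusionMatrix | None = None

    def to_row(self) -> dict[str, float]:
        row = {"accuracy": self.accuracy,
               "weighted_precision": self.weighted_precision,
               "weighted_recall": self.weighted_recall,
               "weighted_f1": self.weighted_f1}
        for c, m in self.per_class.items():
            for name, v in m.items():
                row[f"{name}_{c}"] = v
        for c, v in self.auc.items():
            row[f"auc_{c}"] = v
        return row


def confusion_matrix(actual: Sequence[str], predicted: Sequence[str],
                     class_order: tuple[str, ...]) -> ConfusionMatrix:
    """Count actual-vs-predicted class pairs."""
    if len(actual) != len(predicted):
        raise ConfigurationError("actual and predicted lengths differ")
    lookup = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in lookup or p not in lookup:
            raise DataError(f"label pair ({a!r}, {p!r}) outside class order "
                            f"{class_order}")
        counts[lookup[a], lookup[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Micro accuracy in percent: 100·(correct)/(total)."""
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def macro_ovr_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of per-class one-vs-rest accuracies, in percent.

    With k > 2 classes every misclassification counts as correct for the
    k − 2 uninvolved classes, so this exceeds micro accuracy on imperfect
    matrices; it is provided for comparison only.
    """
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")
    accs = []
    for i in range(len(cm.class_order)):
        tp, tn, fp, fn = cm.one_vs_rest(i)
        accs.append((tp + tn) / cm.total)
    return 100.0 * float(np.mean(accs))


def per_class_prf(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class precision, recall and F1 as fractions.

    precision_i = TP_i/(TP_i + FP_i), recall_i = TP_i/(TP_i + FN_i),
    F1_i their harmonic mean; undefined ratios (empty column or row)
    are reported as 0 with a warning.
    """
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")
    out: dict[str, dict[str, float]] = {}
    for i, c in enumerate(cm.class_order):
        tp, _, fp, fn = cm.one_vs_rest(i)
        if tp + fp == 0:
            warnings.warn(f"class {c!r} never predicted; precision set to 0")
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(f"class {c!r} has no actual instances; recall set to 0")
            recall = 0.0
        else:
            recall = tp / (tp + fn)
        f1 = (0.0 if precision + recall == 0
              else 2 * precision * recall / (precision + recall))
        out[c] = {"precision": precision, "recall": recall, "f1": f1}
    return out


def weighted_prf(cm: ConfusionMatrix) -> dict[str, float]:
    """Support-weighted precision/recall/F1 in percent.

    Weights are the actual class counts y_i. ``f1`` averages the
    per-class F1 values; ``f1_harmonic`` is the harmonic mean of the
    weighted precision and weighted recall, reported as a secondary
    figure.
    """
    per_class = per_class_prf(cm)
    weights = cm.actual_counts.astype(float)
    wsum = weights.sum()
    p = sum(w * per_class[c]["precision"]
            for w, c in zip(weights, cm.class_order)) / wsum
    r = sum(w * per_class[c]["recall"]
            for w, c in zip(weights, cm.class_order)) / wsum
    f = sum(w * per_class[c]["f1"]
            for w, c in zip(weights, cm.class_order)) / wsum
    fh = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return {"precision": 100 * p, "recall": 100 * r, "f1": 100 * f,
            "f1_harmonic": 100 * fh}


def roc_auc(scores: Sequence[float], actual: Sequence[str],
            positive_class: str) -> float:
    """One-vs-rest AUC by the rank statistic.

    The probability that a uniformly chosen positive instance has a
    higher score than a uniformly chosen negative one, ties counted
    half — equal to the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")
    positives = np.array([a == positive_class for a in actual])
    n_pos = int(positives.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError(f"AUC for {positive_class!r} needs both positive and "
                        "negative instances")
    ranks = rankdata(scores)             # midranks handle ties
    rank_sum = float(ranks[positives].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass
class CrossValidationResult:
    """Per-fold reports plus their unweighted aggregate."""

    folds: list[MetricsReport]
    aggregate: MetricsReport
    models: list[DualModel] = field(default_factory=list)


def _score_report(actual: Sequence[str], predicted: Sequence[str],
                  class_order: tuple[str, ...],
                  true_scores: np.ndarray | None = None) -> MetricsReport:
    cm = confusion_matrix(actual, predicted, class_order)
    weighted = weighted_prf(cm)
    auc = {}
    if true_scores is not None:
        for i, c in enumerate(class_order):
            present = any(a == c for a in actual)
            if present and not all(a == c for a in actual):
                auc[c] = roc_auc(true_scores[:, i], actual, c)
    return MetricsReport(accuracy=overall_accuracy(cm),
                         per_class=per_class_prf(cm),
                         weighted_precision=weighted["precision"],
                         weighted_recall=weighted["recall"],
                         weighted_f1=weighted["f1"],
                         weighted_f1_harmonic=weighted["f1_harmonic"],
                         auc=auc, confusion=cm)


def cross_validate(dataset: LabeledDataset, config: RNNConfig, k: int = 5,
                   seed: int = 0,
                   keep_models: bool = False) -> CrossValidationResult:
    """Stratified k-fold evaluation of the dual-network classifier.

    Per fold: min–max normalization is fitted on the training rows only,
    a DualModel is trained on them, and the held-out rows are predicted.
    The aggregate report is the unweighted mean of the fold metrics.
    Fully deterministic for a given (dataset, config, k, seed).
    """
    plan = stratified_kfold(dataset, k, seed)
    folds: list[MetricsReport] = []
    models: list[DualModel] = []
    for fold in range(k):
        train_rows = plan.train_indices(fold)
        test_rows = plan.test_indices[fold]
        norm = fit_minmax(dataset.features, train_rows)
        train = dataset.subset(train_rows)
        train = LabeledDataset(apply_minmax(train.features, norm),
                               train.labels, dataset.class_order,
                               dataset.feature_names)
        fold_seed = (seed * 100003 + 7919 * fold) % 2_000_000_000
        dual = fit_dual(train, config.with_seed(fold_seed), normalization=norm)
        test_features = apply_minmax(dataset.features[test_rows], norm)
        predicted, records = predict(dual, test_features)
        true_scores = np.array([r.T for r in records])
        folds.append(_score_report(list(dataset.labels[test_rows]), predicted,
                                   dataset.class_order, true_scores))
        if keep_models:
            models.append(dual)

    def mean(getter):
        return float(np.mean([getter(f) for f in folds]))

    agg_per_class = {
        c: {m: mean(lambda f: f.per_class[c][m])
            for m in ("precision", "recall", "f1")}
        for c in dataset.class_order
    }
    agg_auc = {c: float(np.mean([f.auc[c] for f in folds if c in f.auc]))
               for c in dataset.class_order
               if any(c in f.auc for f in folds)}
    aggregate = MetricsReport(
        accuracy=mean(lambda f: f.accuracy),
        per_class=agg_per_class,
        weighted_precision=mean(lambda f: f.weighted_precision),
        weighted_recall=mean(lambda f: f.weighted_recall),
        weighted_f1=mean(lambda f: f.weighted_f1),
        weighted_f1_harmonic=mean(lambda f: f.weighted_f1_harmonic),
        auc=agg_auc, confusion=None)
    return CrossValidationResult(folds=folds, aggregate=aggregate,
                                 models=models)
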