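"""Confusion counts, binary performance measures, ROC/AUC, and stratified
cross-validation.

The six measures are accuracy, precision, recall, F-measure, Matthews
correlation coefficient (MCC) and the area under the ROC curve.  Standard
definitions are used throughout: precision = TP/(TP+FP), recall =
TP/(TP+FN).  Any measure with a zero denominator is reported as 0 and
flagged, so a degenerate constant predictor yields 0 precision/recall/MCC
rather than an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .sequence_io import LabeledDataset, ProteinRecord


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive_class: str,
) -> ConfusionCounts:
    """Standard 2x2 cross-tabulation against a designated positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        t_pos = t == positive_class
        p_pos = p == positive_class
        if t_pos and p_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class PerformanceReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float | None = None
    #: measures whose denominator was zero and were reported as 0
    zero_denominator: tuple[str, ...] = ()


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(c: ConfusionCounts) -> PerformanceReport:
    """The five threshold measures from a confusion table."""
    if c.n == 0:
        raise ValueError("empty confusion table")
    flags = []
    accuracy = (c.tp + c.tn) / c.n
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, flags = 0.0, flags + ["precision"]
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, flags = 0.0, flags + ["recall"]
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc, flags = 0.0, flags + ["mcc"]
    return PerformanceReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f_measure(precision, recall),
        mcc=mcc,
        zero_denominator=tuple(flags),
    )


def roc_auc(
    scores: Sequence[float],
    true_labels: Sequence[str],
    positive_class: str,
) -> tuple[float, list[tuple[float, float, float]]]:
    """AUC via the Mann-Whitney rank statistic (ties credited 0.5), plus the
    ROC curve as (threshold, fpr, tpr) points at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = np.asarray([t == positive_class for t in true_labels], dtype=bool)
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    pos, neg = scores[y], scores[~y]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (len(pos) * len(neg))
    fpr, tpr, thresholds = roc_curve(y.astype(int), scores)
    curve = [(float(t), float(f), float(r)) for t, f, r in zip(thresholds, fpr, tpr)]
    return auc, curve


def stratified_kfold(data: LabeledDataset, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Reproducible stratified fold assignment (fold index per record)."""
    y = data.y()
    for c in data.classes:
        if y.count(c) < folds:
            raise ValueError(f"class {c!r} has fewer than {folds} members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


class ClassifierSpec(Protocol):
    """What cross_validate needs from a classifier."""

    def fit(self, train: LabeledDataset): ...

    def predict(
        self, fitted, records: Sequence[ProteinRecord], reference: LabeledDataset
    ) -> tuple[list[str], list[float] | None]: ...


@dataclass
class CrossValidationResult:
    overall: PerformanceReport
    per_fold: list[PerformanceReport]
    pooled_confusion: ConfusionCounts
    predictions: dict[str, str]
    scores: dict[str, float]
    fold_assignment: np.ndarray


def cross_validate(
    data: LabeledDataset,
    model_spec: ClassifierSpec,
    positive_class: str,
    folds: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation with pooled out-of-fold metrics.

    Within each fold the model is fit on the other folds only; any homology
    reference a spec uses is likewise restricted to the training folds
    (specs receive the training split as their reference database).
    """
    assignment = stratified_kfold(data, folds=folds, seed=seed)
    predictions: dict[str, str] = {}
    scores: dict[str, float] = {}
    per_fold: list[PerformanceReport] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in range(folds):
        train_idx = [i for i, f in enumerate(assignment) if f != fold]
        test_idx = [i for i, f in enumerate(assignment) if f == fold]
        train = data.subset(train_idx)
        test_records = [data.records[i] for i in test_idx]
        fitted = model_spec.fit(train)
        labels, fold_scores = model_spec.predict(fitted, test_records, train)
        truth = [data.class_of(r.id) for r in test_records]
        c = confusion(truth, labels, positive_class)
        pooled = pooled + c
        per_fold.append(metrics(c))
        for rec, lab in zip(test_records, labels):
            predictions[rec.id] = lab
        if fold_scores is not None:
            for rec, s in zip(test_records, fold_scores):
                scores[rec.id] = s
    overall = metrics(pooled)
    if scores:
        truth_all = [data.class_of(r.id) for r in data.records]
        score_all = [scores[r.id] for r in data.records]
        try:
            auc, _ = roc_auc(score_all, truth_all, positive_class)
            overall.auc = auc
        except ValueError:
            pass
    return CrossValidationResult(
        overall=overall,
        per_fold=per_fold,
        pooled_confusion=pooled,
        predictions=predictions,
        scores=scores,
        fold_assignment=assignment,
    )


def report_as_dict(report: PerformanceReport) -> dict:
    return {
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "mcc": report.mcc,
        "auc": report.auc,
        "zero_denominator": list(report.zero_denominator),
    }
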