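"""Experiment splits, confusion matrices and the derived performance metrics.

Two experimental designs are supported:

* Experiment I  — train and test share all subjects; within each
  (subject, class) group the first ceil(n/2) segments train and the rest
  test (the "first half of each recording" protocol).
* Experiment II — train and test subjects are disjoint; the split follows
  a per-subject design table.

From a 3x3 confusion matrix (rows = true class, columns = predicted) the
report derives per-class sensitivity 100*TP/(TP+FN), positive predictive
value 100*TP/(TP+FP), per-class TN-based accuracy, and the single headline
"total accuracy" 100*trace/total — the overall fraction of correctly
classified parts, which is the quantity the printed tables carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .core import CLASSES, AudioSegment


__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "ExperimentSplit",
    "make_split",
    "confusion",
    "metrics",
    "roc_one_vs_rest",
]


@dataclass
class ConfusionMatrix:
    """3x3 count table; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass
class MetricReport:
    """Per-class sensitivity / PPV / accuracy and the overall total accuracy (%).

    Metrics undefined because a class has an empty row (no true parts) or
    empty column (no predictions) are NaN and listed in ``undefined``.
    """

    sensitivity_pct: dict[str, float]
    ppv_pct: dict[str, float]
    class_accuracy_pct: dict[str, float]  # TN-based per-class accuracy
    total_accuracy_pct: float
    undefined: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensitivity_pct": self.sensitivity_pct,
                "ppv_pct": self.ppv_pct,
                "class_accuracy_pct": self.class_accuracy_pct,
            }
        )


def confusion(true_labels, predictions, labels: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a ConfusionMatrix."""
    t = np.asarray(true_labels)
    p = np.asarray(predictions)
    if len(t) != len(p):
        raise ValueError("true_labels and predictions differ in length")
    for arr in (t, p):
        unknown = set(arr) - set(labels)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
    if len(t) == 0:
        return ConfusionMatrix(np.zeros((len(labels), len(labels)), dtype=int), labels)
    counts = skmetrics.confusion_matrix(t, p, labels=list(labels))
    return ConfusionMatrix(counts, labels)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity, PPV and accuracy from one confusion matrix."""
    counts = cm.counts
    total = cm.grand_total
    if total == 0:
        raise ValueError("cannot compute metrics of an all-zero confusion matrix")
    sens: dict[str, float] = {}
    ppv: dict[str, float] = {}
    acc: dict[str, float] = {}
    undefined: list[str] = []
    for i, c in enumerate(cm.labels):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
        ppv[c] = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
        acc[c] = 100.0 * (tp + tn) / total
        if math.isnan(sens[c]) or math.isnan(ppv[c]):
            undefined.append(c)
    total_acc = 100.0 * np.trace(counts) / total
    return MetricReport(
        sensitivity_pct=sens,
        ppv_pct=ppv,
        class_accuracy_pct=acc,
        total_accuracy_pct=float(total_acc),
        undefined=undefined,
    )


@dataclass
class ExperimentSplit:
    """Indices of the training and test segments within one dataset."""

    name: str  # "I" | "II"
    train_indices: list[int]
    test_indices: list[int]

    def train(self, segments: list[AudioSegment]) -> list[AudioSegment]:
        return [segments[i] for i in self.train_indices]

    def test(self, segments: list[AudioSegment]) -> list[AudioSegment]:
        return [segments[i] for i in self.test_indices]


def make_split(
    segments: list[AudioSegment],
    experiment: str,
    test_subjects: set[str] | None = None,
) -> ExperimentSplit:
    """Split segments per the Experiment I or II protocol.

    Experiment I: within every (subject, class) group (in segment order) the
    first ceil(n/2) segments train, the rest test.  Experiment II: segments
    of ``test_subjects`` test, all others train; the two subject sets are
    disjoint by construction, and at least one subject must fall on each
    side.
    """
    if experiment not in ("I", "II"):
        raise ValueError("experiment must be 'I' or 'II'")
    if experiment == "I":
        groups: dict[tuple[str, str], list[int]] = {}
        for i, seg in enumerate(segments):
            groups.setdefault((seg.subject_id, seg.label), []).append(i)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for key in groups:
            idx = groups[key]
            n_train = math.ceil(len(idx) / 2)
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
        return ExperimentSplit("I", sorted(train_idx), sorted(test_idx))
    if not test_subjects:
        raise ValueError("Experiment II requires a non-empty set of test subjects")
    all_subjects = {seg.subject_id for seg in segments}
    train_subjects = all_subjects - set(test_subjects)
    if not train_subjects:
        raise ValueError(
            "Experiment II requires disjoint train and test subjects; "
            "no subject is left for training"
        )
    train_idx = [i for i, seg in enumerate(segments) if seg.subject_id in train_subjects]
    test_idx = [i for i, seg in enumerate(segments) if seg.subject_id in test_subjects]
    return ExperimentSplit("II", train_idx, test_idx)


def roc_one_vs_rest(
    decision_values: np.ndarray, true_labels, positive_class: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC curve (FPR, TPR) and trapezoidal area."""
    y = np.asarray(true_labels)
    scores = np.asarray(decision_values, dtype=float)
    pos = y == positive_class
    if pos.all() or not pos.any():
        raise ValueError(f"need both positive and negative examples of {positive_class!r}")
    fpr, tpr, _ = skmetrics.roc_curve(pos.astype(int), scores)
    return fpr, tpr, float(skmetrics.auc(fpr, tpr))
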