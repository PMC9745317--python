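"""Binary classification metric suite.

Per-class precision/recall/F1 follow the confusion-count formulas
(precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = 2tp/(2tp+fp+fn); the
negative class uses the complementary counts). AUROC is the tie-corrected
rank statistic and AUPRC the step-wise average precision, both delegated
to scikit-learn, whose implementations are exactly those estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class MetricsReport:
    positive: ClassMetrics  # promoter class
    negative: ClassMetrics  # non-promoter class
    auroc: float
    auprc: float
    counts: ConfusionCounts


def confusion_counts(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def _prf(tp: int, fp: int, fn: int, support: int) -> ClassMetrics:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return ClassMetrics(precision, recall, f1, support)


def evaluate(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full metric report for promoter probabilities against binary labels.

    Raises if only one class is present (AUROC/AUPRC are undefined there).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; AUROC/AUPRC undefined")
    c = confusion_counts(p, y, threshold)
    return MetricsReport(
        positive=_prf(c.tp, c.fp, c.fn, support=c.tp + c.fn),
        negative=_prf(c.tn, c.fn, c.fp, support=c.tn + c.fp),
        auroc=float(roc_auc_score(y, p)),
        auprc=float(average_precision_score(y, p)),
        counts=c,
    )
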