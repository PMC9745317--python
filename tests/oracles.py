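"""Independent brute-force oracles used by the metric tests."""

import numpy as np


def auroc_pairwise(scores, labels):
    """Mann-Whitney AUROC by explicit pair enumeration (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_stepwise(scores, labels):
    """Step-wise average precision: sum of precision x recall increments,
    evaluated once per distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    n_pos = y.sum()
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap
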