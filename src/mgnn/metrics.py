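"""Ranking metrics for imbalanced node classification.

AUROC is computed from midranks (tie-aware Mann--Whitney statistic);
AUPRC is average precision, the step-wise integral of the
precision--recall curve (no trapezoidal interpolation), with tied scores
collapsed onto one threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return auroc(scores, labels), average_precision(scores, labels)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    y = np.asarray(labels).ravel()
    r = rankdata(scores)                 # midranks
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    # group tied scores onto a single operating point
    distinct = np.where(np.diff(s))[0]
    cut = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y == 1)[cut].astype(float)
    fp = np.cumsum(y == 0)[cut].astype(float)
    n_pos = tp[-1]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))
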