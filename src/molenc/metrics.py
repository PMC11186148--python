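"""Evaluation metrics.

Hand-rolled, order-invariant implementations of the metrics used for
pretraining (masked-symbol recovery accuracy), single-task fine-tuning
(AUROC, AUPRC, MAE, Spearman) and multi-label prediction (macro/micro F1).
Each is cross-checked in the test suite against scikit-learn / SciPy and
against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MetricReport", "recovery_accuracy", "auroc", "auprc", "mae",
    "spearman", "f1_scores", "METRIC_FUNCS",
]


class UndefinedMetricError(ValueError):
    """Metric has no defined value for this input (e.g. one-class AUROC)."""


@dataclass
class MetricReport:
    """Per-fold metric values and their mean, plus free-form notes."""

    metric: str
    fold_values: List[float] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        if not self.fold_values:
            raise ValueError("no fold values recorded")
        return float(np.mean(self.fold_values))

    def to_record(self) -> str:
        lines = [f"metric\t{self.metric}"]
        for i, v in enumerate(self.fold_values):
            lines.append(f"fold{i}\t{v:.6f}")
        lines.append(f"mean\t{self.mean:.6f}")
        for note in self.notes:
            lines.append(f"note\t{note}")
        return "\n".join(lines) + "\n"


def recovery_accuracy(predicted: np.ndarray, targets: np.ndarray,
                      mask_positions: np.ndarray) -> float:
    """Fraction of masked positions whose predicted ID equals the target."""
    predicted = np.asarray(predicted)
    targets = np.asarray(targets)
    mask_positions = np.asarray(mask_positions)
    if len(mask_positions) == 0:
        raise ValueError("mask_positions must be non-empty")
    if len(targets) != len(mask_positions):
        raise ValueError("targets must align with mask_positions")
    return float((predicted[mask_positions] == targets).mean())


def _ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean rank."""
    x = np.asarray(x, dtype=np.float64)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    r = _ranks(scores)
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under precision-recall via threshold stepping.

    Equals sum over descending score thresholds of
    (recall_i - recall_{i-1}) * precision_i; a constant score yields the
    positive prevalence.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], (labels[order] == 1).astype(np.float64)
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # collapse tied thresholds: keep the last index of each distinct score
    distinct = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(((recall - prev_recall) * precision).sum())


def mae(predictions: Sequence[float], truths: Sequence[float]) -> float:
    predictions = np.asarray(predictions, dtype=np.float64)
    truths = np.asarray(truths, dtype=np.float64)
    if predictions.shape != truths.shape:
        raise ValueError("shape mismatch")
    return float(np.abs(predictions - truths).mean())


def spearman(predictions: Sequence[float], truths: Sequence[float]) -> float:
    """Rank correlation with average ranks for ties."""
    predictions = np.asarray(predictions, dtype=np.float64)
    truths = np.asarray(truths, dtype=np.float64)
    if predictions.shape != truths.shape:
        raise ValueError("shape mismatch")
    if len(predictions) < 2:
        raise UndefinedMetricError("Spearman needs at least two samples")
    ra, rb = _ranks(predictions), _ranks(truths)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra ** 2).sum() * (rb ** 2).sum())
    if denom == 0:
        raise UndefinedMetricError("Spearman undefined for constant input")
    return float((ra * rb).sum() / denom)


def f1_scores(probabilities: np.ndarray, labels: np.ndarray,
              threshold: float = 0.5) -> Tuple[float, float]:
    """(macro F1, micro F1) for a multi-label probability matrix.

    Labels with zero predicted and zero true positives contribute F1 = 0
    to the macro average.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    probabilities = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    labels = np.atleast_2d(np.asarray(labels))
    if probabilities.shape != labels.shape:
        raise ValueError("shape mismatch")
    pred = probabilities >= threshold
    truth = labels == 1
    tp = (pred & truth).sum(axis=0).astype(np.float64)
    fp = (pred & ~truth).sum(axis=0).astype(np.float64)
    fn = (~pred & truth).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_label = np.where(2 * tp + fp + fn > 0,
                             2 * tp / np.maximum(2 * tp + fp + fn, 1e-300), 0.0)
    macro = float(per_label.mean())
    tp_all, fp_all, fn_all = tp.sum(), fp.sum(), fn.sum()
    micro = float(2 * tp_all / (2 * tp_all + fp_all + fn_all)) if (
        2 * tp_all + fp_all + fn_all) > 0 else 0.0
    return macro, micro


METRIC_FUNCS = {
    "AUROC": auroc,
    "AUPRC": auprc,
    "MAE": mae,
    "Spearman": spearman,
}
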