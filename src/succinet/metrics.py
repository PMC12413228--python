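"""Binary-classification metrics implemented from first principles.

Eight metrics: accuracy, precision, recall, specificity, F1, Matthews
correlation coefficient (MCC), AUROC and AUPRC. AUROC is computed via
the Mann–Whitney rank statistic with midrank handling of ties; AUPRC is
average precision (step interpolation). Zero-denominator conventions:
precision = 0 when no positive predictions; MCC = 0 when any marginal
of the confusion matrix is empty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    auroc: float | None
    auprc: float | None
    threshold: float = 0.5

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if labels.size == 0:
        raise ValueError("empty input")
    return labels, scores


def confusion_counts(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion-matrix counts; score >= threshold predicts positive."""
    labels, scores = _validate(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 when any denominator factor vanishes."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def auroc(labels, scores) -> float:
    """AUROC via the Mann–Whitney statistic with midrank ties."""
    labels, scores = _validate(labels, scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined for single-class labels")
    ranks = rankdata(scores)  # average (midrank) ties
    rank_sum = float(np.sum(ranks[labels == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_points(labels, scores) -> list[tuple[float, float]]:
    """(FPR, TPR) points swept over all unique score thresholds, plus (0,0)."""
    labels, scores = _validate(labels, scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined for single-class labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(y)):
        tp += int(y[i] == 1)
        fp += int(y[i] == 0)
        if i + 1 == len(y) or s[i + 1] != s[i]:
            points.append((fp / n_neg, tp / n_pos))
    return points


def pr_points(labels, scores) -> list[tuple[float, float]]:
    """(recall, precision) points over unique score thresholds, descending."""
    labels, scores = _validate(labels, scores)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("PR curve undefined for single-class labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    points = []
    tp = 0
    for i in range(len(y)):
        tp += int(y[i] == 1)
        if i + 1 == len(y) or s[i + 1] != s[i]:
            points.append((tp / n_pos, tp / (i + 1)))
    return points


def auprc(labels, scores) -> float:
    """Average precision: sum of precision-at-threshold weighted by recall steps."""
    pts = pr_points(labels, scores)
    ap = 0.0
    prev_recall = 0.0
    for recall, precision in pts:
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """All eight metrics at the given threshold.

    For single-class label vectors the curve areas are undefined and
    reported as ``None`` (not a number); the threshold metrics are still
    computed.
    """
    labels, scores = _validate(labels, scores)
    c = confusion_counts(labels, scores, threshold)
    n = c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    try:
        roc_area = auroc(labels, scores)
        pr_area = auprc(labels, scores)
    except ValueError:
        roc_area = None
        pr_area = None
    return MetricsReport(
        accuracy=(c.tp + c.tn) / n,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        mcc=mcc_from_counts(c),
        auroc=roc_area,
        auprc=pr_area,
        threshold=threshold,
    )


def write_curves(labels, scores, roc_path: str | Path, pr_path: str | Path) -> None:
    """Dump ROC (fpr, tpr) and PR (recall, precision) curves as TSV."""
    with open(roc_path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in roc_points(labels, scores):
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
    with open(pr_path, "w") as fh:
        fh.write("recall\tprecision\n")
        for rec, prec in pr_points(labels, scores):
            fh.write(f"{rec:.10g}\t{prec:.10g}\n")
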