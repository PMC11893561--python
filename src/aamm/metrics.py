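"""Bag-level evaluation metrics: AUC, accuracy, recall, confusion counts.

AUC is computed as the Mann-Whitney rank statistic with tie correction:
the probability that a random positive outscores a random negative,
counting ties as 1/2.  This equals the trapezoidal integral of the ROC
curve; the threshold-sweep form is kept as an independent cross-check
(:func:`auc_trapezoid`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


def _validate_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return scores, labels


def auc(scores, labels) -> float:
    """Rank-statistic AUC (Mann-Whitney U / (n_pos * n_neg)), ties count 1/2."""
    scores, labels = _validate_binary(scores, labels)
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_trapezoid(scores, labels) -> float:
    """Trapezoidal ROC integral via a threshold sweep (cross-check route)."""
    scores, labels = _validate_binary(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y == 1)[cut].astype(float)
    fps = np.cumsum(y == 0)[cut].astype(float)
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return float(np.trapezoid(tpr, fpr))


def confusion_counts(pred_labels, true_labels, positive_class: int = 1):
    """(TP, TN, FP, FN) treating ``positive_class`` as positive."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    p = pred == positive_class
    t = true == positive_class
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    return tp, tn, fp, fn


def accuracy_metric(pred_labels, true_labels) -> float:
    """(TP + TN) / all — the proportion of correctly classified bags."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    return float(np.mean(pred == true))


def recall_metric(pred_labels, true_labels, positive_class: int = 1) -> float:
    """TP / (TP + FN); macro-averaged one-vs-rest when more than two classes."""
    true = np.asarray(true_labels, dtype=int)
    classes = np.unique(true)
    if len(classes) > 2:
        vals = []
        for c in classes:
            tp, _, _, fn = confusion_counts(pred_labels, true_labels, int(c))
            if tp + fn == 0:
                raise ValueError(f"no positives for class {c}")
            vals.append(tp / (tp + fn))
        return float(np.mean(vals))
    tp, _, _, fn = confusion_counts(pred_labels, true_labels, positive_class)
    if tp + fn == 0:
        raise ValueError("no positive samples; recall undefined")
    return float(tp / (tp + fn))


@dataclass
class MetricsReport:
    """Per-fold metric values with mean +/- sd summaries."""

    per_fold: list[dict] = field(default_factory=list)

    def add_fold(self, **metrics) -> None:
        self.per_fold.append(metrics)

    @property
    def metric_names(self) -> list[str]:
        names: list[str] = []
        for fold in self.per_fold:
            for k in fold:
                if k not in names:
                    names.append(k)
        return names

    def mean(self, name: str) -> float:
        return float(np.mean([f[name] for f in self.per_fold]))

    def sd(self, name: str) -> float:
        vals = [f[name] for f in self.per_fold]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict:
        return {name: {"mean": self.mean(name), "sd": self.sd(name)}
                for name in self.metric_names}

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "summary": self.summary()}
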