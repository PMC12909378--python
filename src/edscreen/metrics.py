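"""Evaluation metrics with an unconnected-node penalty.

Network-based activity propagation only yields a probability for nodes that
have at least one neighbor; raising the similarity threshold disconnects
nodes and would flatter a classical ROC computed on the connected remainder.
The modified rates keep unconnected compounds in the denominators:

    mTPR = TP / (TP + FN + NCP)        mFPR = FP / (FP + TN + NCN)

where NCP and NCN count unconnected positives and negatives. The area under
the (mFPR, mTPR) curve — the mROC-AUC — therefore penalizes over-strict
thresholds: the curve's terminal true-positive rate is capped by the
connected fraction of actives. With every node connected the modified
metrics reduce exactly to the classical ones.

``fpr_at_tpr`` is the prioritization-workload metric: the classical false
positive rate at the decision threshold achieving a target recall, with
unconnected (score-less) nodes counted as predicted negative so the metric
is comparable across network-based and model-based approaches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .network import NodePrediction

__all__ = [
    "ExtendedConfusion",
    "extended_confusion",
    "mtpr",
    "mfpr",
    "mroc_auc",
    "fpr_at_tpr",
    "OperatingPoint",
]


@dataclass(frozen=True)
class ExtendedConfusion:
    """Confusion counts extended with unconnected positives/negatives."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    NCP: int = 0
    NCN: int = 0

    @property
    def n_active(self) -> int:
        return self.TP + self.FN + self.NCP

    @property
    def n_inactive(self) -> int:
        return self.FP + self.TN + self.NCN


def extended_confusion(
    preds: Sequence[NodePrediction],
    labels: Mapping[str, int],
    decision_threshold: float,
) -> ExtendedConfusion:
    """Tally the extended confusion at one decision threshold.

    Connected nodes are classified positive iff probability >= threshold;
    unconnected actives go to NCP and unconnected inactives to NCN.
    """
    tp = fp = tn = fn = ncp = ncn = 0
    for p in preds:
        if p.compound_id not in labels:
            raise KeyError(f"no label for {p.compound_id}")
        y = labels[p.compound_id]
        if not p.connected:
            ncp, ncn = ncp + (y == 1), ncn + (y == 0)
        elif p.probability >= decision_threshold:
            tp, fp = tp + (y == 1), fp + (y == 0)
        else:
            fn, tn = fn + (y == 1), tn + (y == 0)
    return ExtendedConfusion(TP=tp, FP=fp, TN=tn, FN=fn, NCP=ncp, NCN=ncn)


def mtpr(c: ExtendedConfusion) -> float:
    """Modified true positive rate: TP / (TP + FN + NCP)."""
    if c.n_active == 0:
        raise ZeroDivisionError("no active compounds")
    return c.TP / c.n_active


def mfpr(c: ExtendedConfusion) -> float:
    """Modified false positive rate: FP / (FP + TN + NCN)."""
    if c.n_inactive == 0:
        raise ZeroDivisionError("no inactive compounds")
    return c.FP / c.n_inactive


def _check_two_classes(preds, labels) -> None:
    ys = {labels[p.compound_id] for p in preds}
    if ys != {0, 1}:
        raise ValueError("need at least one active and one inactive label")


def mroc_auc(preds: Sequence[NodePrediction],
             labels: Mapping[str, int]) -> float:
    """Area under the modified ROC curve.

    Decision thresholds sweep the unique connected-node probabilities plus
    one value above the maximum (classifying every connected node negative).
    Points (mFPR, mTPR) are sorted by mFPR; the curve is anchored at (0, 0)
    and extended horizontally from its terminal point to mFPR = 1, so the
    area lives on the same [0, 1] scale as a classical AUC while unconnected
    nodes permanently cap the achievable mTPR.
    """
    _check_two_classes(preds, labels)
    probs = sorted({p.probability for p in preds if p.connected})
    thresholds = probs + [(probs[-1] + 1.0) if probs else 1.0]
    pts = []
    for t in thresholds:
        c = extended_confusion(preds, labels, t)
        pts.append((mfpr(c), mtpr(c)))
    pts.append((0.0, 0.0))
    pts.sort()
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    if xs[-1] < 1.0:  # horizontal extension at the terminal mTPR
        xs = np.append(xs, 1.0)
        ys = np.append(ys, ys[-1])
    return float(np.trapezoid(ys, xs))


class OperatingPoint(NamedTuple):
    fpr: float
    achieved_tpr: float
    threshold: float
    reachable: bool


def fpr_at_tpr(preds: Sequence[NodePrediction],
               labels: Mapping[str, int],
               target_tpr: float) -> OperatingPoint:
    """Classical FPR at the largest threshold whose recall meets the target.

    Unconnected nodes are scored 0 (predicted negative at any positive
    threshold). If no threshold reaches the target recall — e.g. too many
    actives are unconnected — the point of maximal TPR with the lowest FPR
    among its ties is returned with ``reachable=False``.
    """
    if not 0 < target_tpr <= 1:
        raise ValueError("target_tpr must be in (0, 1]")
    _check_two_classes(preds, labels)
    scores = np.array([p.probability if p.connected else 0.0 for p in preds])
    conn = np.array([p.connected for p in preds])
    y = np.array([labels[p.compound_id] for p in preds])
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    best: OperatingPoint | None = None
    fallback: OperatingPoint | None = None
    thresholds = sorted(set(scores[conn])) if conn.any() else [1.0]
    for t in thresholds:
        pred = conn & (scores >= t)
        tpr = float((pred & (y == 1)).sum() / n_pos)
        fpr = float((pred & (y == 0)).sum() / n_neg)
        if tpr >= target_tpr:
            if best is None or t > best.threshold:
                best = OperatingPoint(fpr, tpr, float(t), True)
        # maximal-TPR fallback: later (larger) thresholds with the same TPR
        # have lower FPR, so >= keeps the lowest-FPR point among ties
        if fallback is None or tpr > fallback.achieved_tpr or (
                tpr == fallback.achieved_tpr and fpr <= fallback.fpr):
            fallback = OperatingPoint(fpr, tpr, float(t), False)
    return best if best is not None else fallback
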