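"""Confusion matrices and abnormal-beat detection metrics.

The five-class confusion matrix (rows: ground truth N, S, V, F, Q;
columns: predicted) is cumulated over the ensemble's runs — each beat is
counted once per trained network.  Collapsing to Normal-vs-Abnormal
(N negative, {S,V,F,Q} positive) gives the 2x2 matrix from which the
standard detection metrics derive:

    Sen = TP/(TP+FN)   Spe = TN/(TN+FP)   Ppr = TP/(TP+FP)
    Acc = (TP+TN)/total               FAR = FP/(TN+FP) = 1 - Spe

The advance-warning statistics follow from the per-beat miss
probability p1 = FN/(TP+FN): under independence across consecutive
abnormal beats the probability of missing three in a row is p1^3, so
the chance of catching at least one of the first three occurrences is
1 - p1^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .beats import AAMI

#: display order of the five classes (ground-truth rows / predicted columns)
CLASS_ORDER = (AAMI.N, AAMI.S, AAMI.V, AAMI.F, AAMI.Q)


@dataclass
class ConfusionMatrix5:
    """5x5 counts indexed by AAMI class value (rows true, cols predicted)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @classmethod
    def zeros(cls) -> "ConfusionMatrix5":
        return cls(np.zeros((5, 5), dtype=np.int64))

    @classmethod
    def from_predictions(cls, true_labels, pred_labels) -> "ConfusionMatrix5":
        cm = np.zeros((5, 5), dtype=np.int64)
        for t, p in zip(true_labels, pred_labels, strict=True):
            cm[int(t), int(p)] += 1
        return cls(cm)

    def __add__(self, other: "ConfusionMatrix5") -> "ConfusionMatrix5":
        return ConfusionMatrix5(self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [c.name for c in CLASS_ORDER]
        idx = [int(c) for c in CLASS_ORDER]
        return pd.DataFrame(self.counts[np.ix_(idx, idx)], index=names,
                            columns=names)


@dataclass
class ConfusionMatrix2:
    """Normal-vs-Abnormal counts (N negative, {S,V,F,Q} positive)."""

    tn: int
    fn: int
    fp: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fn, self.fp, self.tp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp

    def __add__(self, other: "ConfusionMatrix2") -> "ConfusionMatrix2":
        return ConfusionMatrix2(self.tn + other.tn, self.fn + other.fn,
                                self.fp + other.fp, self.tp + other.tp)


@dataclass
class DetectionMetrics:
    """Percentages (acc..far) and probabilities (p_*); None = undefined."""

    acc: Optional[float]
    sen: Optional[float]
    spe: Optional[float]
    ppr: Optional[float]
    far: Optional[float]
    p_miss1: Optional[float]
    p_miss3: Optional[float]
    p_detect_within3: Optional[float]
    p_miss1_trunc3: Optional[float] = None  # fn/(tp+fn) truncated at 3 decimals

    def rounded(self) -> dict:
        """Reporting convention: percentages to 2 decimals, probs to 4."""
        def r(v, nd):
            return None if v is None else round(v, nd)

        return {
            "acc": r(self.acc, 2), "sen": r(self.sen, 2), "spe": r(self.spe, 2),
            "ppr": r(self.ppr, 2), "far": r(self.far, 2),
            "p_miss1": r(self.p_miss1, 4), "p_miss3": r(self.p_miss3, 4),
            "p_detect_within3": r(self.p_detect_within3, 4),
            "p_miss1_trunc3": self.p_miss1_trunc3,
        }


def accumulate(models, xs: np.ndarray, xt: np.ndarray,
               true_labels: np.ndarray) -> ConfusionMatrix5:
    """Cumulated confusion matrix: each beat counted once per model."""
    from .cnn import predict_batch

    if not models:
        raise ValueError("need at least one model")
    cm = ConfusionMatrix5.zeros()
    for model in models:
        pred = predict_batch(model, xs, xt)
        cm = cm + ConfusionMatrix5.from_predictions(true_labels, pred)
    return cm


def collapse(cm5: ConfusionMatrix5) -> ConfusionMatrix2:
    """Fold the five classes into Normal vs Abnormal; total preserved."""
    c = cm5.counts
    n = int(AAMI.N)
    tn = int(c[n, n])
    fp = int(c[n, :].sum() - c[n, n])
    fn = int(c[:, n].sum() - c[n, n])
    tp = int(c.sum() - tn - fp - fn)
    return ConfusionMatrix2(tn=tn, fn=fn, fp=fp, tp=tp)


def metrics(cm2: ConfusionMatrix2) -> DetectionMetrics:
    """Detection metrics from the 2x2 matrix.

    Undefined ratios (no positives, or no negatives, in ground truth)
    are reported as None, never as 0.
    """
    if cm2.total == 0:
        raise ValueError("empty confusion matrix")
    pos = cm2.tp + cm2.fn
    neg = cm2.tn + cm2.fp
    sen = 100.0 * cm2.tp / pos if pos else None
    spe = 100.0 * cm2.tn / neg if neg else None
    far = 100.0 * cm2.fp / neg if neg else None
    ppr = 100.0 * cm2.tp / (cm2.tp + cm2.fp) if (cm2.tp + cm2.fp) else None
    acc = 100.0 * (cm2.tp + cm2.tn) / cm2.total
    p1 = cm2.fn / pos if pos else None
    p3 = p1**3 if p1 is not None else None
    return DetectionMetrics(
        acc=acc, sen=sen, spe=spe, ppr=ppr, far=far,
        p_miss1=p1, p_miss3=p3,
        p_detect_within3=(1.0 - p3) if p3 is not None else None,
        p_miss1_trunc3=(int(p1 * 1000) / 1000.0) if p1 is not None else None,
    )


def per_subject_report(
    subject_cms: Sequence[tuple[str, ConfusionMatrix2]]
) -> pd.DataFrame:
    """Per-subject metric rows plus a pooled row.

    The pooled row applies ``metrics`` to the *sum* of the matrices, not
    the mean of the per-subject metrics.  Subjects without abnormal
    beats report FAR/Spe only (Sen undefined -> NaN); they are the
    cleanest probes of the real false-alarm rate.
    """
    rows = []
    pooled = ConfusionMatrix2(0, 0, 0, 0)
    for sid, cm in subject_cms:
        m = metrics(cm).rounded()
        rows.append({"subject": sid, **m})
        pooled = pooled + cm
    if subject_cms:
        rows.append({"subject": "pooled", **metrics(pooled).rounded()})
    return pd.DataFrame(rows)


def first_alarm_latency(true_labels: np.ndarray, pred_labels: np.ndarray) -> Optional[int]:
    """1-based position of the first detected abnormal beat among the
    true abnormal occurrences; None if no abnormal beat was detected
    (or none occurred)."""
    n = int(AAMI.N)
    pos = 0
    for t, p in zip(true_labels, pred_labels, strict=True):
        if int(t) != n:
            pos += 1
            if int(p) != n:
                return pos
    return None
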