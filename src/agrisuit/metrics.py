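"""Confusion-matrix evaluation metrics, implemented from first principles.

Everything derives from the K x K confusion matrix (rows = reference,
columns = modelled): overall accuracy, Cohen's kappa, the pairwise-average
(Hand-Till) multiclass AUC from class-probability scores, and eleven
one-vs-rest per-class metrics (sensitivity, specificity, PPV, NPV,
precision, recall, F1, prevalence, detection rate, detection prevalence,
balanced accuracy).  Zero-denominator ratios are reported as NaN, never
silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "overall_accuracy",
    "kappa",
    "multiclass_auc",
    "per_class_metrics",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray          # (K, K) int64, rows = reference
    classes: tuple             # fixed class order

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("confusion matrix must be K x K matching the class order")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(reference: Sequence, predicted: Sequence,
              classes: Sequence | None = None) -> ConfusionMatrix:
    """Count table: counts[r, p] = samples with reference r predicted p."""
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted labels differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([ref, pred]))
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, p in zip(ref, pred):
        if r not in index or p not in index:
            raise ValueError(f"label outside class set: {r!r} / {p!r}")
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: probability a sample is modelled correctly."""
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement, in [-1, 1].

    k = (p_o - p_e) / (1 - p_e) with p_o the overall accuracy and p_e the
    expected agreement from the row/column marginals.  When p_e = 1 the
    statistic is undefined; 1.0 is returned for a perfect matrix, else 0.0
    with a warning.
    """
    n = cm.total
    p_o = overall_accuracy(cm)
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        warnings.warn("kappa undefined (chance agreement = 1); returning 0.0",
                      stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _binary_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-statistic AUC with ties counted 0.5 (Mann-Whitney)."""
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    ranks = rankdata(np.concatenate([pos_scores, neg_scores]))
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def multiclass_auc(reference: Sequence, scores: np.ndarray,
                   classes: Sequence | None = None) -> float:
    """Pairwise-average (Hand-Till) multiclass AUC from probability scores.

    ``scores[s, k]`` is sample s's score for class ``classes[k]``.  For each
    unordered class pair (i, j), A(i|j) is the two-class AUC of the class-i
    score restricted to samples of classes i and j, and the pair contributes
    (A(i|j) + A(j|i)) / 2; the result is the mean over all pairs.
    """
    ref = np.asarray(reference)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = np.unique(ref)
    classes = list(classes)
    if scores.ndim != 2 or scores.shape[0] != len(ref) or scores.shape[1] != len(classes):
        raise ValueError("scores must be (n_samples, n_classes) matching the class order")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    pair_aucs = []
    for ki, kj in combinations(range(len(classes)), 2):
        in_i = ref == classes[ki]
        in_j = ref == classes[kj]
        if not in_i.any() or not in_j.any():
            raise ValueError(f"class pair ({classes[ki]!r}, {classes[kj]!r}) "
                             "has a missing class")
        a_ij = _binary_auc(scores[in_i, ki], scores[in_j, ki])
        a_ji = _binary_auc(scores[in_j, kj], scores[in_i, kj])
        pair_aucs.append((a_ij + a_ji) / 2.0)
    return float(np.mean(pair_aucs))


PER_CLASS_COLUMNS = (
    "sensitivity", "specificity", "ppv", "npv", "precision", "recall",
    "f1", "prevalence", "detection_rate", "detection_prevalence",
    "balanced_accuracy",
)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Eleven one-vs-rest metrics per class; NaN on zero denominators."""

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else np.nan

    n = cm.total
    rows = []
    for k, cls in enumerate(cm.classes):
        tp = float(cm.counts[k, k])
        fn = float(cm.counts[k].sum() - tp)
        fp = float(cm.counts[:, k].sum() - tp)
        tn = float(n - tp - fn - fp)
        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        ppv = ratio(tp, tp + fp)
        f1 = ratio(2 * ppv * sens, ppv + sens) \
            if np.isfinite(ppv) and np.isfinite(sens) else np.nan
        rows.append({
            "class": cls,
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": ratio(tn, tn + fn),
            "precision": ppv,
            "recall": sens,
            "f1": f1,
            "prevalence": (tp + fn) / n,
            "detection_rate": tp / n,
            "detection_prevalence": (tp + fp) / n,
            "balanced_accuracy": (sens + spec) / 2.0,
        })
    df = pd.DataFrame(rows).set_index("class")
    n_undef = int(df[list(PER_CLASS_COLUMNS)].isna().sum().sum())
    if n_undef:
        warnings.warn(f"{n_undef} per-class metric(s) undefined (zero denominator); "
                      "reported as NaN", stacklevel=2)
    return df


@dataclass
class MetricsReport:
    """Bundle of overall and per-class evaluation metrics for one model."""

    oa: float
    kappa: float
    auc: float | None
    per_class: pd.DataFrame
    confusion: ConfusionMatrix = field(repr=False)

    def summary_row(self, crop: str = "") -> pd.DataFrame:
        return pd.DataFrame([{"crop": crop, "accuracy": self.oa,
                              "kappa": self.kappa, "multiclass_auc": self.auc}])


def evaluate(reference: Sequence, predicted: Sequence,
             scores: np.ndarray | None = None,
             classes: Sequence | None = None) -> MetricsReport:
    """Full evaluation of predictions against reference labels.

    ``scores`` (probability per class, same class order) enables the
    multiclass AUC; without it the AUC is reported as None.
    """
    cm = confusion(reference, predicted, classes)
    auc = multiclass_auc(reference, scores, cm.classes) if scores is not None else None
    return MetricsReport(oa=overall_accuracy(cm), kappa=kappa(cm), auc=auc,
                         per_class=per_class_metrics(cm), confusion=cm)
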