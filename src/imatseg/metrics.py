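"""Evaluation metrics: Dice overlap, clustering accuracy, NMI, ARI.

Dice scores segmentation overlap; ACC, NMI and ARI score the agreement of
a 2-cluster tissue partition with the reference labels.  NMI uses the
arithmetic mean of the two partition entropies as normalization; ARI is
the pair-counting Rand index with chance correction.  All scores are
invariant to permuting cluster indices (ACC after the cluster-to-label
mapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

NMI_NORMALIZATION = "arithmetic"   # mean of the two partition entropies


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred).astype(bool).ravel()
        truth = np.asarray(truth).astype(bool).ravel()
        if pred.shape != truth.shape:
            raise ValueError("shape mismatch")
        return cls(
            tp=int((pred & truth).sum()), tn=int((~pred & ~truth).sum()),
            fp=int((pred & ~truth).sum()), fn=int((~pred & truth).sum()),
        )


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """2|X & Y| / (|X| + |Y|); 1.0 when both masks are empty."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("masks must share a shape")
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (x & y).sum() / denom)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    return (counts.tp + counts.tn) / counts.total


def clustering_accuracy(
    labels_true: np.ndarray,
    labels_pred: np.ndarray,
    matching: str = "identity",
) -> float:
    """Fraction of agreeing assignments for binary partitions.

    ``matching='identity'`` scores the labels as given (use after the
    majority cluster-to-label mapping); ``'optimal'`` maximizes agreement
    over cluster-index permutations (Hungarian matching).
    """
    a = np.asarray(labels_true).ravel()
    b = np.asarray(labels_pred).ravel()
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("empty partitions")
    if matching == "identity":
        return float((a == b).mean())
    if matching == "optimal":
        ua, ub = np.unique(a), np.unique(b)
        cont = np.array([[np.sum((a == i) & (b == j)) for j in ub] for i in ua])
        r, c = optimize.linear_sum_assignment(-cont)
        return float(cont[r, c].sum() / a.size)
    raise ValueError("matching must be 'identity' or 'optimal'")


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("empty partitions")
    return float(normalized_mutual_info_score(
        a, b, average_method=NMI_NORMALIZATION))


def ari(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index (pair counting with chance correction)."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(adjusted_rand_score(a, b))


def clustering_report(labels_true: np.ndarray, labels_pred: np.ndarray) -> dict:
    """ACC/NMI/ARI for a labeled 2-cluster result, in percent."""
    return {
        "acc_percent": 100.0 * clustering_accuracy(labels_true, labels_pred),
        "nmi_percent": 100.0 * nmi(labels_true, labels_pred),
        "ari_percent": 100.0 * ari(labels_true, labels_pred),
    }
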