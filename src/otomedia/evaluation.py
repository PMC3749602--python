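"""Confusion matrices, accuracy summaries and the two-tailed Fisher test.

Also re-enters, as module constants, the published benchmark in which three
general pediatricians diagnosed the 181-image expert-consensus set
(63 AOM, 70 OME, 48 NOE): pooled counts plus the high- and medium/low-
confidence splits.  Their printed summary percentages (79.6% overall
accuracy, 15.7% OME-as-AOM, 45.8% NOE misdiagnosed, 9 of 24 high-confidence
NOE misdiagnoses) are recomputed from these counts by
:func:`accuracy_summary` and serve as fixed arithmetic checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import scipy.stats

from .core import CLASS_LABELS, REJECTED

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy_summary",
    "fisher_exact_2x2",
    "PEDIATRICIAN_POOLED",
    "PEDIATRICIAN_HIGH_CONFIDENCE",
    "PEDIATRICIAN_MEDIUM_LOW",
]

#: Pooled diagnoses of three general pediatricians (columns: predicted)
#: against the expert-otoscopist ground truth (rows: AOM, OME, NOE).
PEDIATRICIAN_POOLED = np.array(
    [[62, 1, 0],
     [11, 56, 3],
     [4, 18, 26]]
)

#: Same benchmark restricted to diagnoses given with high confidence.
PEDIATRICIAN_HIGH_CONFIDENCE = np.array(
    [[60, 0, 0],
     [6, 37, 1],
     [1, 8, 15]]
)

#: ... and with medium or low confidence.
PEDIATRICIAN_MEDIUM_LOW = np.array(
    [[2, 1, 0],
     [5, 19, 2],
     [3, 10, 11]]
)


def _round1(x: float) -> float:
    """Round half-up to one decimal, matching printed clinical tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """3x3 diagnostic confusion counts; rows = ground truth, columns =
    predicted, both in (AOM, OME, NOE) order.  Rejected images are tallied
    separately and never enter the 3x3 block."""

    counts: np.ndarray
    rejected: int = 0
    labels: tuple = CLASS_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise ValueError("counts must be 3x3")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.rejected < 0:
            raise ValueError("rejected count must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion(labels_true, labels_pred) -> ConfusionMatrix:
    """Tabulate predictions against ground truth.

    ``REJECTED`` predictions are excluded from the 3x3 block and counted in
    ``rejected``; any other label outside AOM/OME/NOE raises.
    """
    labels_true = list(labels_true)
    labels_pred = list(labels_pred)
    if len(labels_true) != len(labels_pred):
        raise ValueError("label sequences must have equal length")
    index = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    counts = np.zeros((3, 3), dtype=int)
    rejected = 0
    for t, p in zip(labels_true, labels_pred):
        if t not in index:
            raise ValueError(f"unknown ground-truth label {t!r}")
        if p == REJECTED:
            rejected += 1
            continue
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, rejected=rejected)


def accuracy_summary(cm: ConfusionMatrix) -> dict:
    """Overall, per-class and per-cell percentages, one-decimal half-up.

    ``overall`` = 100 * trace / total; ``per_class[c]`` = 100 * diagonal /
    row sum; ``misdiagnosis[(true, pred)]`` = 100 * off-diagonal cell / row
    sum.  Classes with an empty ground-truth row are omitted from the
    per-class and per-cell maps.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    out = {
        "overall": _round1(100.0 * np.trace(cm.counts) / cm.total),
        "per_class": {},
        "misdiagnosis": {},
    }
    for i, true_lab in enumerate(cm.labels):
        row = cm.counts[i].sum()
        if row == 0:
            continue
        out["per_class"][true_lab] = _round1(100.0 * cm.counts[i, i] / row)
        for j, pred_lab in enumerate(cm.labels):
            if i != j:
                out["misdiagnosis"][(true_lab, pred_lab)] = _round1(
                    100.0 * cm.counts[i, j] / row
                )
    return out


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 count table.

    Standard two-sided convention: the sum, at fixed margins, of the
    hypergeometric probabilities of all tables no more probable than the
    observed one.  A table with an empty margin carries no evidence of
    association: p = 1 with a warning.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin: p = 1 by convention", RuntimeWarning,
                      stacklevel=2)
        return 1.0
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
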