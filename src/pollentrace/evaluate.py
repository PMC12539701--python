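"""Confusion-matrix metrics, municipality rollup, temporal tables and
test-retest reliability.

Producer-level predictions are summarized by the usual multiclass confusion
matrix statistics (accuracy, balanced accuracy, per-class and macro
precision/recall/F1, weighted F1).  Because each producer belongs to exactly
one municipality, producer predictions double as municipality predictions
after mapping both label vectors through the producer->municipality table —
a coarsening that can only ever raise accuracy.

Test-retest reliability quantifies the stability of the classifier across
the two time-separated acquisition rounds: per-producer F1 scores are
computed separately on round-1 and round-2 test images and their Pearson
correlation

    r12 = sum_i (f_i1 - fbar1)(f_i2 - fbar2)
          / sqrt( sum_i (f_i1 - fbar1)^2 * sum_i (f_i2 - fbar2)^2 )

is reported; r12 near 1 means producers that score well (or badly) do so
consistently in both rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedCorrelationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ReliabilityReport",
    "confusion",
    "metrics",
    "municipality_rollup",
    "temporal_table",
    "test_retest",
    "per_class_f1",
    "pearson_r12",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n, n) ints; rows = true class, columns = predicted
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ContractError(
                f"counts shape {self.counts.shape} does not match {n} classes"
            )
        if np.any(self.counts < 0):
            raise ContractError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    per_class: pd.DataFrame  # index: class; columns: precision, recall, f1, support
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_f1: float


@dataclass
class ReliabilityReport:
    classes: list[str]
    f1_round1: np.ndarray
    f1_round2: np.ndarray
    r12: float


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Count matrix with rows indexed by true class, columns by prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ContractError("y_true and y_pred must have equal length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            bad = t if t not in index else p
            raise ContractError(f"label {bad!r} not in classes")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Confusion-matrix statistics with explicit zero-division conventions.

    A class never predicted has precision 0; a class with P = R = 0 has
    F1 = 0.  Balanced accuracy is the plain mean of per-class recalls;
    weighted F1 weights per-class F1 by true class counts.
    """
    counts = cm.counts.astype(float)
    if cm.total == 0:
        raise ContractError("confusion matrix is empty")
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(diag), where=pr > 0)
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": row.astype(int),
        },
        index=pd.Index(cm.classes, name="class"),
    )
    weights = row / row.sum()
    return MetricsReport(
        accuracy=float(diag.sum() / counts.sum()),
        balanced_accuracy=float(recall.mean()),
        per_class=per_class,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_f1=float((weights * f1).sum()),
    )


def municipality_rollup(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    mapping: Mapping[str, str],
) -> MetricsReport:
    """Metrics after mapping producer labels to their municipalities."""
    try:
        t = [mapping[p] for p in y_true]
        p = [mapping[q] for q in y_pred]
    except KeyError as exc:
        raise ContractError(f"producer {exc.args[0]!r} missing from mapping") from exc
    classes = sorted(set(t) | set(p))
    return metrics(confusion(t, p, classes))


def temporal_table(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    visits: Sequence[int],
) -> pd.DataFrame:
    """Per-visit metric rows: balanced accuracy and weighted recall/precision/F1.

    Weighted recall and precision weight the per-class values by true class
    counts (so weighted recall equals plain accuracy).  Rows are ordered by
    visit number; visits without samples are simply absent.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    visits = np.asarray(visits)
    if not (y_true.shape == y_pred.shape == visits.shape):
        raise ContractError("y_true, y_pred and visits must align")
    rows = []
    for visit in np.unique(visits):
        sel = visits == visit
        classes = sorted(set(y_true[sel]) | set(y_pred[sel]))
        rep = metrics(confusion(y_true[sel], y_pred[sel], classes))
        support = rep.per_class["support"].to_numpy(float)
        weights = support / support.sum()
        rows.append(
            {
                "visit": int(visit),
                "balanced_accuracy": rep.balanced_accuracy,
                "weighted_recall": float(
                    (weights * rep.per_class["recall"].to_numpy(float)).sum()
                ),
                "weighted_precision": float(
                    (weights * rep.per_class["precision"].to_numpy(float)).sum()
                ),
                "weighted_f1": rep.weighted_f1,
            }
        )
    return pd.DataFrame(rows).set_index("visit")


def per_class_f1(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Per-class F1 vector in the order of ``classes``."""
    rep = metrics(confusion(y_true, y_pred, list(classes)))
    return rep.per_class["f1"].to_numpy(float)


def pearson_r12(f1_round1: Sequence[float], f1_round2: Sequence[float]) -> float:
    """Pearson correlation between two per-producer F1 vectors.

    Raises :class:`UndefinedCorrelationError` when either vector is constant.
    """
    a = np.asarray(f1_round1, dtype=float)
    b = np.asarray(f1_round2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("F1 vectors must be 1-d and of equal length")
    c1 = a - a.mean()
    c2 = b - b.mean()
    denom = np.sqrt((c1**2).sum() * (c2**2).sum())
    if denom == 0.0:
        raise UndefinedCorrelationError(
            "per-producer F1 vector is constant in at least one round"
        )
    return float((c1 * c2).sum() / denom)


def test_retest(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    rounds: Sequence[int],
    classes: Optional[Sequence[str]] = None,
) -> ReliabilityReport:
    """Test-retest reliability between acquisition rounds 1 and 2.

    Per-class (producer) F1 is computed separately on the two round subsets
    and correlated across producers.  Raises
    :class:`UndefinedCorrelationError` when either F1 vector is constant —
    the correlation is then undefined and must not be silently reported as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rounds = np.asarray(rounds)
    if not (y_true.shape == y_pred.shape == rounds.shape):
        raise ContractError("y_true, y_pred and rounds must align")
    if classes is None:
        classes = sorted(set(y_true))
    classes = list(classes)
    if len(classes) < 3:
        raise ContractError("test-retest needs at least 3 producers")
    f1 = {}
    for rnd in (1, 2):
        sel = rounds == rnd
        present = set(y_true[sel])
        missing = [c for c in classes if c not in present]
        if missing:
            raise ContractError(
                f"round {rnd} has no test images for producer(s) {missing}"
            )
        f1[rnd] = per_class_f1(y_true[sel], y_pred[sel], classes)
    return ReliabilityReport(classes, f1[1], f1[2], pearson_r12(f1[1], f1[2]))
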