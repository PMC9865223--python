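"""Confusion-matrix accuracy assessment: OA, PA, UA and the Kappa coefficient.

Orientation: rows are the classified labels, columns the ground truth, so for
class i with diagonal count N_ii, row total N_i+ and column total N_+i,

    OA    = trace / N
    PA_i  = N_ii / N_+i        (omission-error complement)
    UA_i  = N_ii / N_i+        (commission-error complement)
    Kappa = (N * trace - sum_i N_i+ * N_+i) / (N^2 - sum_i N_i+ * N_+i)

Full precision is kept internally; report formatting rounds percentages and
Kappa to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class ConfusionMatrix:
    """k x k counts; rows = classified, columns = ground truth."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise DataError(
                f"counts shape {self.counts.shape} does not match {k} classes")
        if (self.counts < 0).any():
            raise DataError("confusion-matrix counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def index_of(self, class_label: str) -> int:
        try:
            return self.classes.index(class_label)
        except ValueError:
            raise DataError(f"unknown class {class_label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(predicted: Sequence[str], truth: Sequence[str],
                     classes: Sequence[str]) -> ConfusionMatrix:
    """counts[i, j] = number of samples classified i whose ground truth is j."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise DataError("predicted and truth label vectors differ in length")
    classes = tuple(classes)
    lut = {c: i for i, c in enumerate(classes)}
    unknown = sorted({*pred.tolist(), *true.tolist()} - set(classes))
    if unknown:
        raise DataError(f"labels outside the class order: {unknown}")
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(pred, true):
        counts[lut[p], lut[t]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of samples on the diagonal."""
    if cm.n == 0:
        raise DataError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.n


def producer_accuracy(cm: ConfusionMatrix, class_label: str) -> float:
    """Diagonal count over the ground-truth (column) total of the class."""
    i = cm.index_of(class_label)
    col = cm.col_totals[i]
    if col == 0:
        raise DataError(f"class {class_label!r} has no ground-truth samples")
    return float(cm.counts[i, i]) / float(col)


def user_accuracy(cm: ConfusionMatrix, class_label: str) -> float:
    """Diagonal count over the classified (row) total of the class."""
    i = cm.index_of(class_label)
    row = cm.row_totals[i]
    if row == 0:
        raise DataError(f"class {class_label!r} was never predicted")
    return float(cm.counts[i, i]) / float(row)


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement computed from the count matrix."""
    n = cm.n
    chance = float(np.dot(cm.row_totals.astype(float),
                          cm.col_totals.astype(float)))
    denom = float(n) ** 2 - chance
    if denom == 0:
        raise DataError("degenerate confusion matrix: kappa undefined")
    return (n * float(np.trace(cm.counts)) - chance) / denom


@dataclass
class AccuracyReport:
    """OA, Kappa and per-class PA/UA, with a plain-text table renderer."""

    cm: ConfusionMatrix
    oa: float
    kappa: float
    pa: dict[str, float]
    ua: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "PA_pct": round(self.pa[c] * 100, 2),
             "UA_pct": round(self.ua[c] * 100, 2)}
            for c in self.cm.classes
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict[str, float]:
        return {"OA_pct": round(self.oa * 100, 2),
                "kappa": round(self.kappa, 2)}

    def format_table(self, display_names: dict[str, str] | None = None) -> str:
        """Aligned text table: counts with ground truth in columns, per-row PA,
        a totals row, a UA row, and the OA/Kappa footer."""
        names = display_names or {}
        classes = self.cm.classes
        header = (["Class"] + [names.get(c, c) for c in classes]
                  + ["Total", "PA/%"])
        body = []
        for i, c in enumerate(classes):
            body.append([names.get(c, c)]
                        + [str(int(v)) for v in self.cm.counts[i]]
                        + [str(int(self.cm.row_totals[i])),
                           f"{self.pa[c] * 100:.2f}"])
        body.append(["Total"] + [str(int(v)) for v in self.cm.col_totals]
                    + [str(self.cm.n), "-"])
        body.append(["UA/%"] + [f"{self.ua[c] * 100:.2f}" for c in classes]
                    + ["-", "-"])
        widths = [max(len(row[j]) for row in [header] + body)
                  for j in range(len(header))]
        lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
        for row in body:
            lines.append("  ".join(v.ljust(w) for v, w in zip(row, widths)))
        lines.append(f"OA: {self.oa * 100:.2f}%  Kappa: {self.kappa:.2f}")
        return "\n".join(lines)


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Full accuracy suite for one confusion matrix.

    Per-class PA/UA are NaN for classes absent from truth or predictions
    rather than raising, so a report can always be rendered.
    """
    pa, ua = {}, {}
    for c in cm.classes:
        i = cm.index_of(c)
        pa[c] = (float(cm.counts[i, i]) / cm.col_totals[i]
                 if cm.col_totals[i] else float("nan"))
        ua[c] = (float(cm.counts[i, i]) / cm.row_totals[i]
                 if cm.row_totals[i] else float("nan"))
    return AccuracyReport(cm=cm, oa=overall_accuracy(cm), kappa=kappa(cm),
                          pa=pa, ua=ua)
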