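"""Three-class evaluation: confusion matrix, per-class sensitivity, accuracy.

Predictions and truth are compared over the classes {MI, MO, TO}; the NT
grade is merged into MO.  The confusion matrix follows the predicted-rows x
true-columns layout.  Percentages are rounded to one decimal with half-up
rounding; extended metrics (precision, specificity) are available in the
text report but sensitivity and overall accuracy are the headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import DworakLabels
from .errors import AlignmentError, EvalError

CLASSES3 = ("MI", "MO", "TO")


def merge_nt(grade: str) -> str:
    """Collapse the four grades onto the three evaluated classes (NT -> MO)."""
    return "MO" if grade == "NT" else grade


def round1(x: float) -> float:
    """Round to one decimal, half-up (so 84.75 -> 84.8, not banker's 84.8/84.7)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts; rows = predicted (MI, MO, TO), columns = true."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (3, 3):
            raise EvalError(f"expected a 3x3 matrix, got shape {counts.shape}")
        if np.any(counts < 0):
            raise EvalError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column_total(self, cls: str) -> int:
        return int(self.counts[:, CLASSES3.index(cls)].sum())

    def row_total(self, cls: str) -> int:
        return int(self.counts[CLASSES3.index(cls), :].sum())

    def diagonal(self, cls: str) -> int:
        i = CLASSES3.index(cls)
        return int(self.counts[i, i])


def confusion_matrix(
    pred: Mapping[str, str] | Sequence[str], truth: DworakLabels
) -> ConfusionMatrix3:
    """Tally predicted x true counts over {MI, MO, TO}.

    ``pred`` is either a mapping sample_id -> label or a sequence aligned to
    ``truth.sample_ids``.  NT in the truth is counted in the MO column.
    """
    if isinstance(pred, Mapping):
        if set(pred) != set(truth.sample_ids):
            raise AlignmentError("prediction and truth sample sets differ")
        pred_labels = [pred[s] for s in truth.sample_ids]
    else:
        pred_labels = list(pred)
        if len(pred_labels) != len(truth):
            raise AlignmentError(
                f"{len(pred_labels)} predictions for {len(truth)} samples"
            )
    counts = np.zeros((3, 3), dtype=int)
    for p, t in zip(pred_labels, truth.grades):
        if p not in CLASSES3:
            raise EvalError(f"predicted label {p!r} not in {CLASSES3}")
        counts[CLASSES3.index(p), CLASSES3.index(merge_nt(t))] += 1
    return ConfusionMatrix3(counts)


def class_sensitivity(cm: ConfusionMatrix3, cls: str) -> float:
    """Per-true-class recall as a percentage, one decimal, half-up."""
    if cls not in CLASSES3:
        raise EvalError(f"class must be one of {CLASSES3}")
    denom = cm.column_total(cls)
    if denom == 0:
        raise EvalError(f"sensitivity undefined: no true {cls} samples")
    return round1(100.0 * cm.diagonal(cls) / denom)


def overall_accuracy(cm: ConfusionMatrix3) -> float:
    """100 x trace / total, one decimal, half-up."""
    if cm.total == 0:
        raise EvalError("overall accuracy undefined for an empty matrix")
    return round1(100.0 * np.trace(cm.counts) / cm.total)


def evaluation_report(cm: ConfusionMatrix3) -> str:
    """Plain-text report: predicted-rows x true-columns table, per-class
    sensitivities, overall accuracy, plus an extended precision/specificity
    section.  Undefined metrics are flagged rather than raised."""
    lines = ["confusion matrix (rows = predicted, columns = true)"]
    lines.append("\t" + "\t".join(CLASSES3))
    for i, cls in enumerate(CLASSES3):
        lines.append(cls + "\t" + "\t".join(str(c) for c in cm.counts[i]))
    lines.append("")
    for cls in CLASSES3:
        try:
            sens = class_sensitivity(cm, cls)
            lines.append(f"sensitivity[{cls}]\t{sens}")
        except EvalError:
            lines.append(f"sensitivity[{cls}]\tundefined (no true {cls})")
    lines.append(f"overall_accuracy\t{overall_accuracy(cm)}")
    lines.append("")
    lines.append("extended metrics")
    for cls in CLASSES3:
        row = cm.row_total(cls)
        diag = cm.diagonal(cls)
        prec = f"{round1(100.0 * diag / row)}" if row else "undefined"
        neg = cm.total - cm.column_total(cls)
        tn = neg - (row - diag)
        spec = f"{round1(100.0 * tn / neg)}" if neg else "undefined"
        lines.append(f"precision[{cls}]\t{prec}")
        lines.append(f"specificity[{cls}]\t{spec}")
    return "\n".join(lines) + "\n"


def write_confusion_matrix(cm: ConfusionMatrix3, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("predicted\\true\t" + "\t".join(CLASSES3) + "\n")
        for i, cls in enumerate(CLASSES3):
            fh.write(cls + "\t" + "\t".join(str(c) for c in cm.counts[i]) + "\n")
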