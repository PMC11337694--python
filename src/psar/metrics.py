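"""Binary classification metrics from a confusion matrix.

Accuracy, precision, recall (sensitivity), specificity and F1 are the
standard ratios of true/false positive/negative counts.  A metric whose
denominator is zero is reported as ``None`` ("undefined") rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts; all non-negative, total > 0."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def classification_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Compute the five ratio metrics; undefined ones are ``None``.

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)
    """

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "precision": precision,
        "recall": recall,
        "specificity": ratio(c.tn, c.tn + c.fp),
        "f1": f1,
    }
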