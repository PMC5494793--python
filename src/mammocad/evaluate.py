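"""Confusion-matrix bookkeeping and the nine evaluation metrics.

Metrics (all percentages): sensitivity SNS, specificity SPC, positive /
negative predictive value PPV / NPV, false-positive / false-negative rate
FPR / FNR, false discovery / omission rate FDR / FOR, and accuracy ACC.

For a C-class confusion matrix the default pooling is *micro-averaging*:
one-vs-rest TP/FP/FN/TN are summed over classes before the metric formulas
are applied.  Under micro-averaging TP = trace, FP = FN = total - trace and
TN = C*total - TP - FP - FN, which forces SNS = PPV = ACC and SPC = NPV —
the identity pattern visible in published multi-class metric tables.
Macro-averaging (unweighted per-class mean) is provided for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io_dataset import ValidationError

METRIC_NAMES = ("SNS", "SPC", "PPV", "NPV", "FPR", "FNR", "FDR", "FOR", "ACC")


@dataclass
class ConfusionMatrix:
    """Square count table: rows = actual class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.labels = tuple(self.labels)
        c = len(self.labels)
        if self.counts.shape != (c, c):
            raise ValidationError(
                f"confusion matrix shape {self.counts.shape} does not match "
                f"{c} labels"
            )
        if np.any(self.counts < 0):
            raise ValidationError("confusion matrix entries must be >= 0")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValidationError("cannot add matrices with different labels")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """trace / total, as a fraction."""
        return float(np.trace(self.counts)) / self.total


def accumulate(preds, truths, labels) -> ConfusionMatrix:
    """Count (actual, predicted) pairs into a ConfusionMatrix."""
    labels = tuple(labels)
    preds = list(preds)
    truths = list(truths)
    if len(preds) != len(truths):
        raise ValidationError("preds and truths must have equal length")
    pos = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truths, preds):
        if t not in pos or p not in pos:
            raise ValidationError(f"label {t if t not in pos else p!r} not in {labels}")
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(counts, labels)


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (table display convention)."""
    return math.floor(x * 100 + 0.5) / 100


def _metrics_from_counts(tp: float, tn: float, fp: float, fn: float) -> dict:
    def ratio(a: float, b: float) -> float:
        return 100.0 * a / b if b > 0 else 0.0

    return {
        "SNS": ratio(tp, tp + fn),
        "SPC": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "FPR": ratio(fp, fp + tn),
        "FNR": ratio(fn, tp + fn),
        "FDR": ratio(fp, tp + fp),
        "FOR": ratio(fn, tn + fn),
        "ACC": ratio(tp + tn, tp + tn + fp + fn),
    }


@dataclass
class MetricsReport:
    """The nine metrics as percentages (full precision; 2-dp display)."""

    values: dict[str, float]

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError as exc:
            raise AttributeError(name) from exc

    def rounded(self) -> dict[str, float]:
        return {k: _round2(v) for k, v in self.values.items()}


def micro_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Micro-averaged metrics: pooled one-vs-rest counts over all classes.

    ACC is the plain multi-class accuracy trace/total (= micro SNS = micro
    PPV), the convention under which published multi-class metric tables
    show SNS = PPV = ACC on every row.
    """
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    C = len(cm.labels)
    tp = float(np.trace(cm.counts))
    fn = fp = float(total - tp)
    tn = float(C * total) - tp - fp - fn
    vals = _metrics_from_counts(tp, tn, fp, fn)
    vals["ACC"] = 100.0 * tp / total
    return MetricsReport(vals)


def macro_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Macro-averaged metrics: unweighted mean of per-class one-vs-rest values.

    Classes with zero actual samples are excluded from the mean (warned).
    """
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    per_class: list[dict[str, float]] = []
    for k, lab in enumerate(cm.labels):
        row = float(cm.counts[k].sum())
        if row == 0:
            warnings.warn(
                f"class {lab!r} has no actual samples; excluded from macro mean",
                stacklevel=2,
            )
            continue
        tp = float(cm.counts[k, k])
        fn = row - tp
        fp = float(cm.counts[:, k].sum()) - tp
        tn = float(total) - tp - fn - fp
        per_class.append(_metrics_from_counts(tp, tn, fp, fn))
    vals = {m: float(np.mean([pc[m] for pc in per_class])) for m in METRIC_NAMES}
    return MetricsReport(vals)
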