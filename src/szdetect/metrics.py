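"""Binary-classification metric suite and confusion-count reconstruction.

The suite is accuracy, precision, recall (sensitivity) and the Matthews
correlation coefficient:

    accuracy  = (TP + TN) / N
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    mcor      = (TP*TN - FP*FN) /
                sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Counts are integers for real evaluations but real-valued counts are
allowed, so printed rates from a results table can be inverted back into
(fractional) confusion counts and audited for internal consistency.
Any metric whose denominator vanishes is defined as 0 (with a log note)
so batch evaluation never aborts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "compute_metrics",
           "confusion_from_rates", "counts_from_predictions", "mean_report",
           "reports_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN; real-valued entries allowed for rate reconstruction."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"count {name.upper()}={v} must be finite and >= 0")
        if not self.n > 0:
            raise ValueError("total count N must be positive")

    @property
    def n(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The evaluation suite; ``loss`` is the mean cross-entropy when known."""

    accuracy: float
    precision: float
    recall: float
    mcor: float
    loss: float | None = None


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.info("%s has zero denominator; defining it as 0", name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts,
                    loss: float | None = None) -> MetricsReport:
    """Evaluate the metric suite on confusion counts.

    Zero denominators (precision, recall, or any Matthews factor) yield
    the defined value 0 for that metric.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    mcor_den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return MetricsReport(
        accuracy=(tp + tn) / counts.n,
        precision=_ratio(tp, tp + fp, "precision"),
        recall=_ratio(tp, tp + fn, "recall"),
        mcor=_ratio(tp * tn - fp * fn, math.sqrt(mcor_den_sq), "mcor"),
        loss=loss,
    )


def counts_from_predictions(y_true: np.ndarray,
                            y_pred: np.ndarray) -> ConfusionCounts:
    """Integer confusion counts from binary label vectors (1 = seizure)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


class InconsistentRatesError(ValueError):
    """Printed rates imply a negative confusion count."""


def confusion_from_rates(accuracy: float, recall: float, precision: float,
                         n: float, prevalence: float
                         ) -> tuple[ConfusionCounts, float]:
    """Invert printed accuracy/recall/precision into real-valued counts.

    With P = prevalence * n positives:

        TP = recall * P,  FN = P - TP,
        FP = TP * (1 - precision) / precision,
        TN = accuracy * n - TP.

    Returns the counts and the consistency residual
    ``|TP + TN + FP + FN - n|`` — nonzero when the printed (rounded)
    rates are not exactly realizable at this n and prevalence.
    """
    for name, v in (("accuracy", accuracy), ("recall", recall),
                    ("precision", precision)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    if n <= 0 or prevalence <= 0:
        raise ValueError("n and prevalence must be positive")
    p = prevalence * n
    tp = recall * p
    fp = tp * (1.0 - precision) / precision
    fn = p - tp
    tn = accuracy * n - tp
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise InconsistentRatesError(
                f"reconstruction yields negative {name} = {v:.4f}; the rates "
                f"are inconsistent at N={n}, prevalence={prevalence}"
            )
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return counts, abs(counts.n - n)


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of per-run metrics (not metrics of pooled counts)."""
    if not reports:
        raise ValueError("no reports to average")
    losses = [r.loss for r in reports if r.loss is not None]
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        mcor=float(np.mean([r.mcor for r in reports])),
        loss=float(np.mean(losses)) if losses else None,
    )


def reports_to_frame(rows: list[dict]):
    """Results-table CSV writer: model, fc_size, loss, accuracy, recall,
    precision, mcor columns from dicts holding a MetricsReport."""
    import pandas as pd

    out = []
    for row in rows:
        rep: MetricsReport = row["report"]
        out.append({
            "model": row.get("model", ""),
            "fc_size": row.get("fc_size", ""),
            "loss": rep.loss,
            "accuracy": rep.accuracy,
            "recall": rep.recall,
            "precision": rep.precision,
            "mcor": rep.mcor,
        })
    return pd.DataFrame(out, columns=["model", "fc_size", "loss", "accuracy",
                                      "recall", "precision", "mcor"])
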