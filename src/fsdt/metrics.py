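"""Evaluation suite: confusion counts, accuracy/precision/recall/F1,
training rate, analysis ratio and wall-clock stage timing.

Accuracy, precision, recall and F1 follow the standard confusion-matrix
closed forms. Two quantities are reported as dimensionless fractions whose
exact formulas the package defines canonically (both are config-overridable):

* training rate — the final training-set accuracy of the classifier run,
  with iterations-to-0.9-accuracy as a secondary learning-speed figure;
* analysis ratio — the fraction of retained sections classified decisively,
  i.e. whose probability sits at least ``margin`` away from 0.5. It measures
  the method's ability to eliminate ambiguous section calls.

Undefined ratios (zero denominators) are returned as ``None`` — flagged,
never NaN.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict
from typing import Callable, Iterable, Literal

import numpy as np

from fsdt.cnn import TrainingRecord
from fsdt.detect import DetectionResult

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics",
           "training_rate", "analysis_ratio", "timed"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    level: Literal["image", "section"] = "image"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Aggregated metrics for one evaluation run; ``None`` marks an
    undefined ratio, and ``analysis_time_ms`` is informational only."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    training_rate: float | None = None
    analysis_ratio: float | None = None
    analysis_time_ms: float | None = None
    n_units: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(predictions: Iterable[int], truths: Iterable[int],
              level: Literal["image", "section"] = "image") -> ConfusionCounts:
    """Exact confusion counts over aligned binary prediction/truth lists."""
    pred = np.asarray(list(predictions), dtype=int)
    true = np.asarray(list(truths), dtype=int)
    if pred.size != true.size:
        raise ValueError(f"length mismatch: {pred.size} predictions, {true.size} truths")
    if pred.size == 0:
        raise ValueError("need at least one prediction")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("predictions and truths must be binary {0, 1}")
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, level=level)


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, recall, F1 from confusion counts.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R); any ratio with a zero denominator comes back ``None``.
    """
    if counts.total <= 0:
        raise ValueError("confusion table is empty")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    accuracy = (tp + tn) / counts.total
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall,
                        f1=f1, n_units=counts.total)


def training_rate(record: TrainingRecord,
                  threshold: float = 0.9) -> tuple[float, int, bool]:
    """Learning-efficiency figures of one training run.

    Returns ``(rate, iterations_to_threshold, reached)``: the rate is the
    final training-set accuracy; the secondary figure is the first iteration
    at which the per-batch accuracy reached ``threshold`` (or
    ``iterations_run`` with ``reached=False`` if it never did).
    """
    if not record.acc_curve:
        raise ValueError("empty training record")
    rate = record.final_training_accuracy
    hits = [i + 1 for i, a in enumerate(record.acc_curve) if a >= threshold]
    if hits:
        return rate, hits[0], True
    return rate, record.iterations_run, False


def analysis_ratio(results: list[DetectionResult], margin: float = 0.2) -> float:
    """Fraction of retained sections with a decisive probability.

    A section counts as decisive when ``|prob - 0.5| >= margin``; the ratio
    pools every retained section across the given results.
    """
    if not (0.0 < margin < 0.5):
        raise ValueError(f"margin must lie in (0, 0.5), got {margin}")
    if not results:
        raise ValueError("no detection results given")
    probs = [s.probability for r in results for s in r.per_section]
    if not probs:
        raise ValueError("results contain no retained sections")
    decisive = sum(abs(p - 0.5) >= margin for p in probs)
    return decisive / len(probs)


def timed(stage_fn: Callable, *args, **kwargs):
    """Run a stage and return ``(result, elapsed_ms)`` on the monotonic clock."""
    t0 = time.monotonic()
    result = stage_fn(*args, **kwargs)
    return result, (time.monotonic() - t0) * 1000.0
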