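"""Epoch-based and event-based evaluation of seizure decisions.

Epoch-based criteria over 4-s analysis windows:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / total     G-mean = sqrt(sens * spec)

all reported as percentages.  Event-based criteria: a maximal run of
positive epochs is one detected event; a reference (expert-marked) event
counts as detected when at least one detected event overlaps it, and a
detected event overlapping no reference event is one false positive.  The
false detection rate is false positives per hour of evaluated recording;
across patients the summary is the unweighted mean of per-patient rates,
while event sensitivity pools events (total detected / total marked).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .postprocess import DecisionSeries

__all__ = [
    "ConfusionCounts",
    "EpochMetrics",
    "SeizureEvent",
    "EventMetrics",
    "confusion_counts",
    "epoch_metrics",
    "extract_events",
    "event_metrics",
    "aggregate_epoch_metrics",
    "aggregate_event_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class EpochMetrics:
    """Epoch-based percentages; full precision, round only for display."""

    sensitivity: float
    specificity: float
    accuracy: float
    g_mean: float


@dataclass(frozen=True)
class SeizureEvent:
    """A contiguous seizure interval in seconds, detected or reference."""

    start_s: float
    end_s: float
    source: str = "detected"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty event ({self.start_s}, {self.end_s})")

    def overlaps(self, other: "SeizureEvent") -> bool:
        return min(self.end_s, other.end_s) > max(self.start_s, other.start_s)


@dataclass(frozen=True)
class EventMetrics:
    n_reference: int
    n_detected_true: int
    event_sensitivity: float  # percent
    n_false_positives: int
    fdr_per_hour: float
    hours_evaluated: float


def confusion_counts(labels: Sequence[int], decisions: Sequence[int]) -> ConfusionCounts:
    """Per-epoch confusion counts from ground-truth labels and decisions."""
    y = np.asarray(labels, dtype=int)
    d = np.asarray(decisions, dtype=int)
    if y.shape != d.shape:
        raise ValueError("labels and decisions must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (d == 1))),
        FN=int(np.sum((y == 1) & (d == 0))),
        TN=int(np.sum((y == 0) & (d == 0))),
        FP=int(np.sum((y == 0) & (d == 1))),
    )


def epoch_metrics(counts: ConfusionCounts) -> EpochMetrics:
    """Sensitivity, specificity, accuracy and G-mean as percentages."""
    if counts.TP + counts.FN == 0:
        raise ValueError("no seizure epochs: sensitivity undefined")
    if counts.TN + counts.FP == 0:
        raise ValueError("no nonseizure epochs: specificity undefined")
    sens = 100.0 * counts.TP / (counts.TP + counts.FN)
    spec = 100.0 * counts.TN / (counts.TN + counts.FP)
    acc = 100.0 * (counts.TP + counts.TN) / counts.total
    return EpochMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        g_mean=float(np.sqrt(sens * spec)),
    )


def gmean_percent(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity given as percentages."""
    return float(np.sqrt(sensitivity * specificity))


def extract_events(decisions: DecisionSeries | Sequence[int],
                   epoch_len_s: float = 4.0,
                   start_times_s: Sequence[float] | None = None,
                   source: str = "detected") -> list[SeizureEvent]:
    """Maximal runs of positive epochs become events [first start, last end)."""
    if isinstance(decisions, DecisionSeries):
        dec = decisions.decisions
        epoch_len_s = decisions.epoch_len_s
        start_times_s = decisions.start_times_s
    else:
        dec = np.asarray(decisions, dtype=int)
    starts = (
        np.asarray(start_times_s, dtype=float)
        if start_times_s is not None
        else np.arange(len(dec)) * epoch_len_s
    )
    events: list[SeizureEvent] = []
    run_start: int | None = None
    for i, v in enumerate(dec):
        if v == 1 and run_start is None:
            run_start = i
        elif v == 0 and run_start is not None:
            events.append(SeizureEvent(starts[run_start], starts[i - 1] + epoch_len_s, source))
            run_start = None
    if run_start is not None:
        events.append(SeizureEvent(starts[run_start], starts[len(dec) - 1] + epoch_len_s, source))
    return events


def event_metrics(
    detected: Sequence[SeizureEvent],
    reference: Sequence[SeizureEvent],
    hours_evaluated: float,
) -> EventMetrics:
    """Event sensitivity and false detections per hour.

    Each reference event is counted once, as detected, when any detected
    event overlaps it; each detected event overlapping no reference event
    is one false positive.
    """
    if hours_evaluated <= 0:
        raise ValueError("hours_evaluated must be positive")
    n_ref = len(reference)
    n_true = sum(1 for r in reference if any(d.overlaps(r) for d in detected))
    n_fp = sum(1 for d in detected if not any(d.overlaps(r) for r in reference))
    sens = 100.0 * n_true / n_ref if n_ref else 0.0
    return EventMetrics(
        n_reference=n_ref,
        n_detected_true=n_true,
        event_sensitivity=sens,
        n_false_positives=n_fp,
        fdr_per_hour=n_fp / hours_evaluated,
        hours_evaluated=hours_evaluated,
    )


def aggregate_epoch_metrics(per_patient: Sequence[EpochMetrics]) -> EpochMetrics:
    """Unweighted column means across patients (the usual summary row)."""
    if not per_patient:
        raise ValueError("nothing to aggregate")
    return EpochMetrics(
        sensitivity=float(np.mean([m.sensitivity for m in per_patient])),
        specificity=float(np.mean([m.specificity for m in per_patient])),
        accuracy=float(np.mean([m.accuracy for m in per_patient])),
        g_mean=float(np.mean([m.g_mean for m in per_patient])),
    )


def aggregate_event_metrics(per_patient: Sequence[EventMetrics]) -> EventMetrics:
    """Cross-patient summary: pooled event sensitivity, mean per-patient FDR.

    Event sensitivity pools events (total detected / total marked) while
    the false-detection-rate summary is the unweighted mean of the
    per-patient hourly rates.
    """
    if not per_patient:
        raise ValueError("nothing to aggregate")
    n_ref = sum(m.n_reference for m in per_patient)
    n_true = sum(m.n_detected_true for m in per_patient)
    hours = sum(m.hours_evaluated for m in per_patient)
    return EventMetrics(
        n_reference=n_ref,
        n_detected_true=n_true,
        event_sensitivity=100.0 * n_true / n_ref if n_ref else 0.0,
        n_false_positives=sum(m.n_false_positives for m in per_patient),
        fdr_per_hour=float(np.mean([m.fdr_per_hour for m in per_patient])),
        hours_evaluated=hours,
    )
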