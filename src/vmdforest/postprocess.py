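"""Turning per-epoch class probabilities into binary seizure decisions.

Stages: (1) the probability margin, P(seizure) - P(nonseizure), per epoch;
(2) a linear moving-average filter y_k = (1/(2M+1)) * sum_{i=-M..M} y_{k+i}
that removes short glitches in the margin; (3) a threshold comparison
giving binary decisions; (4) a collar that extends every detected run on
both sides to recover onset/offset epochs blurred by the smoothing.

The smoothing length (odd, at most 35 epochs) and the threshold are tuned
per patient on training data by exhaustive grid search, maximizing the
epoch-level G-mean so the tuning is robust to the heavy seizure/nonseizure
class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbSeries",
    "PostprocessParams",
    "DecisionSeries",
    "prob_margin",
    "moving_average",
    "tune_params",
    "apply_decision",
    "collar_extend",
    "postprocess",
]


@dataclass
class ProbSeries:
    """Per-epoch classifier margin y = P(seizure) - P(nonseizure) in [-1, 1]."""

    margin: np.ndarray
    epoch_len_s: float = 4.0

    def __post_init__(self) -> None:
        self.margin = np.asarray(self.margin, dtype=float)
        if np.any(np.abs(self.margin) > 1 + 1e-9):
            raise ValueError("margins must lie in [-1, 1]")


@dataclass(frozen=True)
class PostprocessParams:
    """Tuned postprocessing parameters.

    ``M`` is the smoothing half-width (window 2M+1 epochs, capped at 35);
    ``collar_epochs`` defaults to M, compensating the smoothing lag.
    """

    M: int
    threshold: float
    collar_epochs: int

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if 2 * self.M + 1 > 35:
            raise ValueError("smoothing window 2M+1 must be <= 35")
        if self.collar_epochs < 0:
            raise ValueError("collar_epochs must be >= 0")


@dataclass
class DecisionSeries:
    """Binary per-epoch decisions (1 = seizure)."""

    decisions: np.ndarray
    epoch_len_s: float = 4.0
    start_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.decisions = np.asarray(self.decisions, dtype=int)
        if not np.isin(self.decisions, (0, 1)).all():
            raise ValueError("decisions must be binary")
        if self.start_times_s is None:
            self.start_times_s = np.arange(len(self.decisions)) * self.epoch_len_s
        else:
            self.start_times_s = np.asarray(self.start_times_s, dtype=float)


def prob_margin(proba_rows: np.ndarray, epoch_len_s: float = 4.0) -> ProbSeries:
    """Margin series from two-class probability rows.

    With rows [P(nonseizure), P(seizure)] summing to 1 the margin equals
    2 * P(seizure) - 1.
    """
    proba = np.atleast_2d(np.asarray(proba_rows, dtype=float))
    if proba.shape[1] != 2:
        raise ValueError("expected two-class probability rows")
    sums = proba.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (+/- 1e-6)")
    return ProbSeries(margin=proba[:, 1] - proba[:, 0], epoch_len_s=epoch_len_s)


def moving_average(series: np.ndarray, M: int) -> np.ndarray:
    """Linear moving-average filter with half-width M.

    Interior points average the full 2M+1 window; at the boundaries only
    the in-range samples are averaged (truncated window), so a constant
    series stays constant everywhere.
    """
    y = np.asarray(series, dtype=float)
    if y.size == 0:
        raise ValueError("series is empty")
    if M < 0:
        raise ValueError("M must be >= 0")
    if M == 0:
        return y.copy()
    kernel = np.ones(2 * M + 1)
    # full convolution sliced to the centered window works for any M,
    # including windows longer than the series
    sums = np.convolve(y, kernel, mode="full")[M : M + y.size]
    counts = np.convolve(np.ones_like(y), kernel, mode="full")[M : M + y.size]
    return sums / counts


def apply_decision(
    smoothed: np.ndarray, threshold: float, epoch_len_s: float = 4.0,
    start_times_s: np.ndarray | None = None,
) -> DecisionSeries:
    """Binary decision per epoch: 1 iff the smoothed margin exceeds the
    threshold (strictly — ties go to nonseizure, the conservative class)."""
    smoothed = np.asarray(smoothed, dtype=float)
    return DecisionSeries(
        decisions=(smoothed > threshold).astype(int),
        epoch_len_s=epoch_len_s,
        start_times_s=start_times_s,
    )


def collar_extend(decisions: DecisionSeries | np.ndarray, collar_epochs: int) -> DecisionSeries:
    """Extend every maximal run of 1s by ``collar_epochs`` on each side.

    Extensions are clipped to the series bounds; runs whose extensions
    touch or overlap merge into one.  The operation is monotone (never
    clears a 1).
    """
    if collar_epochs < 0:
        raise ValueError("collar_epochs must be >= 0")
    if isinstance(decisions, DecisionSeries):
        dec, eln, starts = decisions.decisions, decisions.epoch_len_s, decisions.start_times_s
    else:
        dec = np.asarray(decisions, dtype=int)
        eln, starts = 4.0, None
    out = dec.copy()
    if collar_epochs > 0:
        idx = np.flatnonzero(dec == 1)
        for i in idx:
            lo = max(0, i - collar_epochs)
            hi = min(len(out), i + collar_epochs + 1)
            out[lo:hi] = 1
    return DecisionSeries(decisions=out, epoch_len_s=eln, start_times_s=starts)


def _gmean(labels: np.ndarray, decisions: np.ndarray) -> float:
    pos = labels == 1
    neg = ~pos
    sens = float(np.mean(decisions[pos] == 1))
    spec = float(np.mean(decisions[neg] == 0))
    return float(np.sqrt(sens * spec))


def tune_params(
    train_margin: np.ndarray | ProbSeries,
    train_labels: np.ndarray,
    max_window: int = 35,
    collar_epochs: int | None = None,
) -> PostprocessParams:
    """Grid-search the smoothing window and threshold on training data.

    Every odd window length 1, 3, …, ``max_window`` is paired with every
    candidate threshold (margin quantiles plus a fixed -0.9 … 0.9 grid);
    the pair maximizing the epoch-level G-mean wins, with ties broken by
    the smaller window and then the lower threshold.  ``collar_epochs``
    defaults to the selected M, compensating the smoothing lag.
    """
    margin = train_margin.margin if isinstance(train_margin, ProbSeries) else np.asarray(
        train_margin, dtype=float
    )
    labels = np.asarray(train_labels, dtype=int)
    if margin.shape != labels.shape:
        raise ValueError("margin and labels must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("training labels contain a single class")

    quantiles = np.quantile(margin, np.linspace(0.05, 0.95, 19))
    fixed = np.arange(-0.9, 0.95, 0.1)
    thresholds = np.unique(np.round(np.concatenate([quantiles, fixed]), 12))

    best = (-np.inf, None)
    for M in range((max_window + 1) // 2):  # windows 1, 3, ..., max_window
        smoothed = moving_average(margin, M)
        for thr in thresholds:
            score = _gmean(labels, (smoothed > thr).astype(int))
            if score > best[0] + 1e-12:
                best = (score, (M, float(thr)))
    assert best[1] is not None
    M, thr = best[1]
    return PostprocessParams(
        M=M, threshold=thr,
        collar_epochs=M if collar_epochs is None else collar_epochs,
    )


def postprocess(
    proba_rows: np.ndarray,
    params: PostprocessParams,
    epoch_len_s: float = 4.0,
    start_times_s: np.ndarray | None = None,
) -> dict[str, object]:
    """Run the full chain and return every stage for inspection.

    Returns a dict with keys ``margin``, ``smoothed``, ``thresholded``
    (DecisionSeries before the collar) and ``decisions`` (after).
    """
    series = prob_margin(proba_rows, epoch_len_s=epoch_len_s)
    smoothed = moving_average(series.margin, params.M)
    raw = apply_decision(smoothed, params.threshold, epoch_len_s, start_times_s)
    final = collar_extend(raw, params.collar_epochs)
    return {
        "margin": series.margin,
        "smoothed": smoothed,
        "thresholded": raw,
        "decisions": final,
    }
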