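"""Reading EEG recordings and segmenting them into fixed-length labeled epochs.

Two plain-text carriers are supported: single-channel recordings with one
sample value per line (the format used by the classic intracranial
single-channel epilepsy sets) and multichannel CSV with a header row of
channel names.  Expert seizure annotations are lists of ``(start_s, end_s)``
intervals in seconds from the start of the record; intervals are half-open
``[start, end)`` and times are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecord",
    "AnnotationSet",
    "EpochSeries",
    "FormatError",
    "read_single_channel_text",
    "read_multichannel_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "segment_epochs",
    "label_epochs",
]


class FormatError(ValueError):
    """Raised when an input file does not match its expected plain-text format."""


@dataclass(frozen=True)
class EEGRecord:
    """A multichannel sampled EEG signal.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``, microvolt-scale values.
    fs
        Sampling rate in Hz, strictly positive.
    channel_names
        One identifier per channel.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if samples.shape[0] == 1 and samples.shape[1] > 1 and self.samples.ndim == 1:
            samples = samples.T
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[0] < 1 or samples.shape[1] < 1:
            raise ValueError("samples must be a non-empty (n_samples, n_channels) array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        names = tuple(self.channel_names) or tuple(
            f"ch{i + 1}" for i in range(samples.shape[1])
        )
        if len(names) != samples.shape[1]:
            raise ValueError("channel_names length does not match n_channels")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class AnnotationSet:
    """Expert-marked seizure intervals, seconds from record start."""

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        ivals = tuple(sorted((float(a), float(b)) for a, b in self.intervals))
        for start, end in ivals:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval ({start}, {end})")
        for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("annotation intervals overlap")
        object.__setattr__(self, "intervals", ivals)

    def validate_against(self, record: EEGRecord) -> None:
        for _, end in self.intervals:
            if end > record.duration_s + 1e-9:
                raise ValueError(
                    f"annotation end {end} s exceeds record duration {record.duration_s} s"
                )


@dataclass
class EpochSeries:
    """Contiguous non-overlapping epochs cut from one record.

    ``labels`` is a binary vector (1 = seizure) or ``None`` when the series
    has not been labeled yet.  Every epoch holds exactly
    ``floor(epoch_len_s * fs)`` samples.
    """

    epochs: list[np.ndarray]
    epoch_len_s: float
    fs: float
    start_times_s: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.epochs):
                raise ValueError("labels length must match number of epochs")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[1]


def read_single_channel_text(path: str | Path, fs: float = 173.6) -> EEGRecord:
    """Read a one-sample-per-line plain-text recording into a 1-channel record.

    Blank lines are ignored; any other unparseable line raises
    :class:`FormatError` naming the offending line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno} is not a number: {stripped!r}"
                ) from None
    if not values:
        raise FormatError(f"{path}: file contains no samples")
    return EEGRecord(np.asarray(values)[:, None], fs=fs, channel_names=(path.stem,))


def read_multichannel_csv(path: str | Path, fs: float) -> EEGRecord:
    """Read a header + numeric rows CSV into a multichannel record."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    if frame.shape[0] < 1 or frame.shape[1] < 1:
        raise FormatError(f"{path}: no data rows")
    try:
        samples = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    if not np.all(np.isfinite(samples)):
        raise FormatError(f"{path}: non-finite or missing cell")
    return EEGRecord(samples, fs=fs, channel_names=tuple(map(str, frame.columns)))


def write_multichannel_csv(path: str | Path, record: EEGRecord) -> None:
    pd.DataFrame(record.samples, columns=list(record.channel_names)).to_csv(
        path, index=False
    )


def read_annotations_csv(path: str | Path) -> AnnotationSet:
    """Read seizure intervals from a CSV with ``start_s,end_s`` columns."""
    frame = pd.read_csv(path)
    if not {"start_s", "end_s"} <= set(frame.columns):
        raise FormatError(f"{path}: expected columns start_s,end_s")
    return AnnotationSet(tuple(zip(frame["start_s"], frame["end_s"])))


def write_annotations_csv(path: str | Path, annotations: AnnotationSet) -> None:
    pd.DataFrame(annotations.intervals, columns=["start_s", "end_s"]).to_csv(
        path, index=False
    )


def segment_epochs(record: EEGRecord, epoch_len_s: float = 4.0) -> EpochSeries:
    """Cut a record into contiguous non-overlapping epochs.

    Each epoch holds ``floor(epoch_len_s * fs)`` samples so that non-integer
    products (e.g. 4 s at 173.6 Hz -> 694.4) give a fixed epoch length.  The
    trailing remainder shorter than one epoch is dropped.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    n_epochs = int(np.floor(record.duration_s / epoch_len_s + 1e-12))
    if n_epochs < 1:
        raise ValueError(
            f"record of {record.duration_s:.3f} s is shorter than one "
            f"{epoch_len_s} s epoch"
        )
    epoch_samples = int(np.floor(epoch_len_s * record.fs + 1e-9))
    epochs = [
        record.samples[i * epoch_samples : (i + 1) * epoch_samples]
        for i in range(n_epochs)
    ]
    starts = np.arange(n_epochs) * epoch_len_s
    return EpochSeries(epochs=epochs, epoch_len_s=epoch_len_s, fs=record.fs,
                       start_times_s=starts)


def label_epochs(
    series: EpochSeries,
    annotations: AnnotationSet,
    min_overlap_s: float = 0.0,
) -> EpochSeries:
    """Attach binary seizure labels to an epoch series.

    An epoch is labeled 1 when its ``[start, start + epoch_len)`` window
    overlaps any annotated interval by strictly more than ``min_overlap_s``
    seconds (default: any positive overlap marks the epoch as seizure).
    """
    labels = np.zeros(len(series), dtype=int)
    for i, start in enumerate(series.start_times_s):
        end = start + series.epoch_len_s
        for a_start, a_end in annotations.intervals:
            overlap = min(end, a_end) - max(start, a_start)
            if overlap > min_overlap_s:
                labels[i] = 1
                break
    return EpochSeries(
        epochs=series.epochs,
        epoch_len_s=series.epoch_len_s,
        fs=series.fs,
        start_times_s=series.start_times_s,
        labels=labels,
    )
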