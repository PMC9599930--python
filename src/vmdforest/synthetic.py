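"""Synthetic EEG with known seizure annotations.

Background activity is 1/f^beta ("pink-like") noise produced by spectrally
shaping seeded white noise, which reproduces the broadband, low-frequency
dominated character of interictal intracranial EEG.  During each seizure
interval a harmonic-rich rhythmic oscillation (fundamental in the 3-5 Hz
spike-wave band plus a few harmonics) is added, scaled to a chosen multiple
of the background RMS and ramped linearly over 2 s at onset and offset to
mimic the gradual evolution of real seizures.  A white sensor-noise floor
at a configurable SNR completes the record.

Annotations equal the requested intervals exactly, so every pipeline stage
can be tested against known ground truth without any external recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .eeg_io import AnnotationSet, EEGRecord, EpochSeries, label_epochs, segment_epochs

__all__ = ["SeizureSpec", "SynthConfig", "generate_record", "generate_dataset"]


@dataclass(frozen=True)
class SeizureSpec:
    """One scripted seizure: onset/duration in seconds, rhythmic fundamental
    in the 3-5 Hz spike-wave band, amplitude as a multiple of background RMS."""

    onset_s: float
    duration_s: float
    oscillation_hz: float = 3.5
    amplitude_ratio: float = 5.0
    n_harmonics: int = 3

    def __post_init__(self) -> None:
        if self.onset_s < 0 or self.duration_s <= 0:
            raise ValueError("seizure must have onset >= 0 and positive duration")
        if self.amplitude_ratio < 1:
            raise ValueError("amplitude_ratio must be >= 1")
        if not (3.0 <= self.oscillation_hz <= 5.0):
            raise ValueError("oscillation_hz must lie in the 3-5 Hz band")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults emulate a focal intracranial montage: 256 Hz sampling, three
    focal channels, 1/f background at a 50 uV RMS scale, seizures at five
    times the background RMS, and a 15 dB white sensor-noise floor.
    """

    fs: float = 256.0
    n_channels: int = 3
    duration_s: float = 600.0
    background_exponent: float = 1.0
    background_scale_uv: float = 50.0
    seizures: tuple[SeizureSpec, ...] = ()
    snr_db: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_channels < 1 or self.duration_s <= 0:
            raise ValueError("fs, n_channels and duration_s must be positive")
        spans = sorted((s.onset_s, s.onset_s + s.duration_s) for s in self.seizures)
        for start, end in spans:
            if end > self.duration_s:
                raise ValueError("seizure interval extends past the record end")
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("seizure intervals overlap")


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise; zero DC."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shaping, n)
    return shaped / shaped.std()


def _seizure_waveform(rng: np.random.Generator, t: np.ndarray, spec: SeizureSpec) -> np.ndarray:
    """Harmonic-rich unit-RMS oscillation with 2-s linear on/off ramps."""
    wave = np.zeros_like(t)
    for h in range(spec.n_harmonics + 1):
        phase = rng.uniform(0, 2 * np.pi)
        wave += (1.0 / (h + 1)) * np.sin(2 * np.pi * spec.oscillation_hz * (h + 1) * t + phase)
    ramp_s = min(2.0, spec.duration_s / 2.0)
    rel = t - t[0]
    ramp = np.minimum(1.0, np.minimum(rel, spec.duration_s - rel) / ramp_s)
    ramp = np.clip(ramp, 0.0, 1.0)
    wave *= ramp
    rms = np.sqrt(np.mean(wave**2))
    return wave / rms if rms > 0 else wave


def generate_record(config: SynthConfig) -> tuple[EEGRecord, AnnotationSet]:
    """Generate one multichannel record plus its exact annotations.

    All randomness flows from ``config.seed``; per-channel sub-streams are
    derived deterministically so identical configs give identical records.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    channels = []
    for _ch in range(config.n_channels):
        background = config.background_scale_uv * _pink_noise(
            rng, n, config.fs, config.background_exponent
        )
        signal = background.copy()
        bg_rms = np.sqrt(np.mean(background**2))
        for spec in config.seizures:
            i0 = int(round(spec.onset_s * config.fs))
            i1 = min(n, int(round((spec.onset_s + spec.duration_s) * config.fs)))
            wave = _seizure_waveform(rng, t[i0:i1], spec)
            # amplitude_ratio is ictal-to-interictal amplitude: at ratio 1 the
            # segment is indistinguishable from background (no added rhythm)
            signal[i0:i1] += (spec.amplitude_ratio - 1.0) * bg_rms * wave
        noise_rms = bg_rms / (10.0 ** (config.snr_db / 20.0))
        signal += noise_rms * rng.standard_normal(n)
        channels.append(signal)
    record = EEGRecord(
        np.column_stack(channels),
        fs=config.fs,
        channel_names=tuple(f"focal{i + 1}" for i in range(config.n_channels)),
    )
    annotations = AnnotationSet(
        tuple((s.onset_s, s.onset_s + s.duration_s) for s in config.seizures)
    )
    return record, annotations


def _balance_classes(series: EpochSeries, rng: np.random.Generator) -> EpochSeries:
    """Subsample the majority class to equal per-class epoch counts."""
    assert series.labels is not None
    pos = np.flatnonzero(series.labels == 1)
    neg = np.flatnonzero(series.labels == 0)
    if len(pos) == 0:
        raise ValueError("no seizure epochs available for training")
    if len(neg) == 0:
        raise ValueError("no nonseizure epochs available for training")
    k = min(len(pos), len(neg))
    keep = np.sort(np.concatenate([
        rng.choice(pos, size=k, replace=False),
        rng.choice(neg, size=k, replace=False),
    ]))
    return EpochSeries(
        epochs=[series.epochs[i] for i in keep],
        epoch_len_s=series.epoch_len_s,
        fs=series.fs,
        start_times_s=series.start_times_s[keep],
        labels=series.labels[keep],
    )


def generate_dataset(
    config_train: SynthConfig,
    config_test: SynthConfig,
    epoch_len_s: float = 4.0,
) -> tuple[EpochSeries, EpochSeries]:
    """Segmented, labeled train/test epoch series from two records.

    The training series is balanced (equal seizure/nonseizure counts by
    seeded subsampling of the majority class), matching the protocol of
    training on a seizure event plus the same amount of nonseizure data;
    the test series is left imbalanced, as deployment data would be.
    """
    train_record, train_ann = generate_record(config_train)
    test_record, test_ann = generate_record(config_test)
    train = label_epochs(segment_epochs(train_record, epoch_len_s), train_ann)
    test = label_epochs(segment_epochs(test_record, epoch_len_s), test_ann)
    rng = np.random.default_rng(config_train.seed + 1)
    return _balance_classes(train, rng), test
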