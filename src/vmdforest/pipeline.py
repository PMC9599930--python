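"""End-to-end orchestration: train a detector, run it, evaluate it.

Training fixes three artifacts on the training data: (1) the VMD mode
selection (average correlation of each frequency-sorted mode with its
epoch signal, screened at the correlation threshold), (2) the fitted deep
forest, trained on class-balanced epochs, and (3) the postprocessing
parameters (smoothing window, threshold, collar), tuned on the margins of
the full time-ordered training series.  Detection reuses all three; every
intermediate stage (raw margin, smoothed margin, thresholded and collared
decisions) is kept for inspection.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import yaml

from . import deep_forest, lecm, metrics, postprocess, vmd
from .eeg_io import AnnotationSet, EEGRecord, EpochSeries, label_epochs, segment_epochs
from .synthetic import SynthConfig

logger = logging.getLogger("vmdforest")

__all__ = [
    "PipelineConfig",
    "DetectorArtifacts",
    "DetectionResult",
    "extract_features",
    "select_modes",
    "train_detector",
    "run_detector",
    "evaluate_run",
    "save_artifacts",
    "load_artifacts",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the detector in one serializable object."""

    epoch_len_s: float = 4.0
    vmd: vmd.VMDConfig = field(default_factory=vmd.VMDConfig)
    correlation_threshold: float = 0.3
    min_modes: int = 2
    grain: deep_forest.GrainConfig = field(default_factory=deep_forest.GrainConfig)
    cascade: deep_forest.CascadeConfig = field(default_factory=deep_forest.CascadeConfig)
    max_smoothing_window: int = 35
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, cascade=replace(self.cascade, seed=seed))

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["grain"]["window_lengths"] = list(self.grain.window_lengths)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["vmd"] = vmd.VMDConfig(**payload.get("vmd", {}))
        grain = payload.get("grain", {})
        if "window_lengths" in grain:
            grain["window_lengths"] = tuple(grain["window_lengths"])
        payload["grain"] = deep_forest.GrainConfig(**grain)
        payload["cascade"] = deep_forest.CascadeConfig(**payload.get("cascade", {}))
        return cls(**payload)


@dataclass
class DetectorArtifacts:
    """Everything needed to run the detector on new records."""

    model: deep_forest.CascadeModel
    params: postprocess.PostprocessParams
    selected_indices: list[int]
    config: PipelineConfig
    fs: float
    n_channels: int


@dataclass
class DetectionResult:
    """All stages of one detection run, for Fig.-style inspection."""

    margin: np.ndarray
    smoothed: np.ndarray
    thresholded: postprocess.DecisionSeries
    decisions: postprocess.DecisionSeries
    events: list[metrics.SeizureEvent]
    start_times_s: np.ndarray


def _decompose_epochs(
    series: EpochSeries, config: PipelineConfig
) -> list[list[vmd.VMFSet]]:
    """One VMD per epoch per channel; reused for selection and features."""
    out = []
    for epoch in series.epochs:
        out.append([
            vmd.decompose(epoch[:, ch], series.fs, config.vmd)
            for ch in range(epoch.shape[1])
        ])
    return out


def select_modes(
    decompositions: Sequence[Sequence[vmd.VMFSet]],
    series: EpochSeries,
    config: PipelineConfig,
) -> list[int]:
    """Average per-mode correlation over training epochs and channels,
    then keep modes above the correlation threshold.

    At least ``config.min_modes`` modes are always kept (highest mean
    correlation first) because the downstream covariance needs two or more
    time-frequency columns.
    """
    K = config.vmd.K
    sums = np.zeros(K)
    count = 0
    for epoch, per_channel in zip(series.epochs, decompositions):
        for ch, vmfs in enumerate(per_channel):
            signal = epoch[:, ch]
            if signal.std() == 0:
                continue
            sums += vmd.mode_correlations(vmfs, signal)
            count += 1
    if count == 0:
        raise ValueError("all training epochs are constant")
    mean_corr = sums / count
    selected = vmd.select_by_correlation(mean_corr, config.correlation_threshold)
    if len(selected) < config.min_modes:
        ranked = np.argsort(mean_corr)[::-1][: config.min_modes]
        selected = sorted(int(i) for i in ranked)
    return selected


def extract_features(
    decompositions: Sequence[Sequence[vmd.VMFSet]],
    selected_indices: Sequence[int],
) -> np.ndarray:
    """LECM feature matrix (n_epochs, d(d+1)/2) from cached decompositions."""
    rows = []
    for per_channel in decompositions:
        tf = vmd.build_tf_matrix(list(per_channel), selected_indices)
        rows.append(lecm.half_vectorize(lecm.matrix_log(lecm.covariance(tf))))
    return np.vstack(rows)


def _fit_grain_to_dimension(
    grain: deep_forest.GrainConfig, d: int
) -> deep_forest.GrainConfig:
    """Drop scanning windows wider than the feature vector.

    Window choice must respect the input dimension; when the tuned mode
    selection yields a shorter feature than the configured windows, the
    oversized windows are clipped to the dimension itself.
    """
    kept = tuple(w for w in grain.window_lengths if w <= d)
    if not kept:
        kept = (d,)
    if kept == grain.window_lengths:
        return grain
    logger.info("clipped scanning windows %s -> %s for %d-dim features",
                grain.window_lengths, kept, d)
    return replace(grain, window_lengths=kept)


def _balanced_indices(labels: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    k = min(len(pos), len(neg))
    if k == 0:
        raise ValueError("training data contain a single class")
    return np.sort(np.concatenate([
        rng.choice(pos, size=k, replace=False),
        rng.choice(neg, size=k, replace=False),
    ]))


def train_detector(
    record: EEGRecord,
    annotations: AnnotationSet,
    config: PipelineConfig | None = None,
) -> DetectorArtifacts:
    """Fit all detector artifacts on one annotated training record.

    Mode selection and postprocessing parameters are tuned on the full
    time-ordered training series; the deep forest is fitted on a
    class-balanced subset of its epochs.
    """
    config = config or PipelineConfig()
    annotations.validate_against(record)
    t0 = time.time()
    series = label_epochs(segment_epochs(record, config.epoch_len_s), annotations)
    assert series.labels is not None
    if len(np.unique(series.labels)) < 2:
        raise ValueError("training record does not contain both classes")

    decomps = _decompose_epochs(series, config)
    logger.info("decomposed %d epochs x %d channels in %.1fs",
                len(series), series.n_channels, time.time() - t0)
    selected = select_modes(decomps, series, config)
    features = extract_features(decomps, selected)
    logger.info("selected modes %s; features %s", selected, features.shape)

    balanced = _balanced_indices(series.labels, config.seed)
    grain = _fit_grain_to_dimension(config.grain, features.shape[1])
    model = deep_forest.fit_cascade(
        features[balanced], series.labels[balanced], grain, config.cascade
    )
    logger.info("cascade grown to %d level(s)", model.n_levels)

    proba = deep_forest.predict_proba(model, features)
    margin = postprocess.prob_margin(proba, epoch_len_s=config.epoch_len_s)
    params = postprocess.tune_params(
        margin, series.labels, max_window=config.max_smoothing_window
    )
    logger.info("tuned postprocessing: %s (%.1fs total)", params, time.time() - t0)
    return DetectorArtifacts(
        model=model,
        params=params,
        selected_indices=list(selected),
        config=config,
        fs=record.fs,
        n_channels=record.n_channels,
    )


def run_detector(record: EEGRecord, artifacts: DetectorArtifacts) -> DetectionResult:
    """Run the trained detector over a record, keeping every stage output."""
    if abs(record.fs - artifacts.fs) > 1e-9:
        raise ValueError(
            f"record sampling rate {record.fs} differs from training rate {artifacts.fs}"
        )
    if record.n_channels != artifacts.n_channels:
        raise ValueError(
            f"record has {record.n_channels} channel(s); detector was trained on "
            f"{artifacts.n_channels}"
        )
    config = artifacts.config
    series = segment_epochs(record, config.epoch_len_s)
    decomps = _decompose_epochs(series, config)
    features = extract_features(decomps, artifacts.selected_indices)
    proba = deep_forest.predict_proba(artifacts.model, features)
    stages = postprocess.postprocess(
        proba, artifacts.params,
        epoch_len_s=config.epoch_len_s,
        start_times_s=series.start_times_s,
    )
    decisions: postprocess.DecisionSeries = stages["decisions"]  # type: ignore[assignment]
    events = metrics.extract_events(decisions)
    return DetectionResult(
        margin=stages["margin"],  # type: ignore[arg-type]
        smoothed=stages["smoothed"],  # type: ignore[arg-type]
        thresholded=stages["thresholded"],  # type: ignore[arg-type]
        decisions=decisions,
        events=events,
        start_times_s=series.start_times_s,
    )


def evaluate_run(
    decisions: postprocess.DecisionSeries,
    annotations: AnnotationSet,
    hours_evaluated: float | None = None,
) -> dict[str, object]:
    """Epoch- and event-based report of one detection run."""
    labels_series = label_epochs(
        EpochSeries(
            epochs=[np.zeros((1, 1))] * len(decisions.decisions),
            epoch_len_s=decisions.epoch_len_s,
            fs=1.0,
            start_times_s=decisions.start_times_s,
        ),
        annotations,
    )
    assert labels_series.labels is not None
    counts = metrics.confusion_counts(labels_series.labels, decisions.decisions)
    epoch = metrics.epoch_metrics(counts)
    hours = (
        hours_evaluated
        if hours_evaluated is not None
        else len(decisions.decisions) * decisions.epoch_len_s / 3600.0
    )
    reference = [
        metrics.SeizureEvent(a, b, source="reference") for a, b in annotations.intervals
    ]
    detected = metrics.extract_events(decisions)
    event = metrics.event_metrics(detected, reference, hours)
    return {"counts": counts, "epoch": epoch, "event": event}


def save_artifacts(path: str | Path, artifacts: DetectorArtifacts) -> None:
    joblib.dump(artifacts, path)


def load_artifacts(path: str | Path) -> DetectorArtifacts:
    return joblib.load(path)
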