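"""Deep-forest classifier: multigrain scanning plus an adaptive cascade.

The deep forest is a non-neural deep ensemble.  A sliding window
(multigrain scanning) turns the raw feature vector into class-probability
features: each window of the vector is classified by a random forest and a
completely-random forest, and all window probabilities are concatenated.
The scanned representation then enters a cascade of levels, each holding
two random forests and two completely-random forests.  A level's input is
the scanned vector concatenated with the previous level's class vectors;
during training the class vectors are out-of-fold cross-validation
predictions so later levels never see resubstitution probabilities.  The
cascade grows adaptively: when mean cross-validated accuracy stops
improving the growth stops and the best-performing depth is kept.

Completely-random ("full random") forests split each node on one randomly
chosen feature at a random threshold and are grown to purity
(ExtraTreesClassifier with max_features=1); random forests use the usual
sqrt(d) feature subsampling.  All randomness flows from one integer seed,
so equal seeds give bit-identical predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

__all__ = [
    "GrainConfig",
    "CascadeConfig",
    "CascadeModel",
    "MultigrainScanner",
    "multigrain_scan",
    "fit_cascade",
    "predict_proba",
    "scanned_length",
]


@dataclass(frozen=True)
class GrainConfig:
    """Multigrain-scanning settings.

    ``window_lengths`` are used in the given (descending) order; each grain
    feeds one random forest and one completely-random forest.
    """

    window_lengths: tuple[int, ...] = (5, 3)
    stride: int = 1
    n_scan_forests: int = 2
    trees_per_forest: int = 120

    def __post_init__(self) -> None:
        if not self.window_lengths:
            raise ValueError("need at least one window length")
        if any(w < 1 for w in self.window_lengths):
            raise ValueError("window lengths must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.trees_per_forest < 1:
            raise ValueError("trees_per_forest must be >= 1")


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade-growth settings.

    Each level has ``forests_per_level`` forests (half random, half
    completely random) of ``trees_per_forest`` trees.  Growth stops after
    ``patience`` levels without a mean-CV-accuracy improvement larger than
    ``improve_tol``, or at ``max_levels``.
    """

    forests_per_level: int = 4
    trees_per_forest: int = 120
    cv_folds: int = 3
    max_levels: int = 20
    patience: int = 1
    improve_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trees_per_forest < 1:
            raise ValueError("trees_per_forest must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        if self.forests_per_level < 2 or self.forests_per_level % 2:
            raise ValueError("forests_per_level must be an even number >= 2")


def _window_starts(d: int, w: int, stride: int) -> np.ndarray:
    if w > d:
        raise ValueError(f"window length {w} exceeds feature dimension {d}")
    return np.arange(0, d - w + 1, stride)


def _windowed(X: np.ndarray, w: int, stride: int) -> tuple[np.ndarray, int]:
    """Stack every length-w window of every row: (n * n_windows, w)."""
    starts = _window_starts(X.shape[1], w, stride)
    blocks = [X[:, s : s + w] for s in starts]
    return np.concatenate(blocks, axis=0), len(starts)


def _make_forest(kind: str, n_trees: int, seed: int):
    if kind == "random":
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )
    # completely-random: one random feature per split, random threshold,
    # grown to purity
    return ExtraTreesClassifier(
        n_estimators=n_trees, max_features=1, random_state=seed, n_jobs=1
    )


class MultigrainScanner:
    """Fits per-grain scanning forests and transforms vectors into
    concatenated window class probabilities."""

    def __init__(self, config: GrainConfig, n_classes: int, seed: int):
        self.config = config
        self.n_classes = n_classes
        self.seed = seed
        self.forests_: dict[int, list] = {}
        self.d_in_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MultigrainScanner":
        X = np.asarray(X, dtype=float)
        self.d_in_ = X.shape[1]
        for gi, w in enumerate(self.config.window_lengths):
            Xw, n_windows = _windowed(X, w, self.config.stride)
            yw = np.tile(y, n_windows)
            forests = []
            for fi in range(self.config.n_scan_forests):
                kind = "random" if fi % 2 == 0 else "completely_random"
                forest = _make_forest(
                    kind, self.config.trees_per_forest, self.seed + 1000 * gi + fi
                )
                forest.fit(Xw, yw)
                forests.append(forest)
            self.forests_[w] = forests
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.d_in_ is None:
            raise RuntimeError("scanner is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.d_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match fitted {self.d_in_}"
            )
        n = X.shape[0]
        parts = []
        for w in self.config.window_lengths:  # descending order by convention
            Xw, n_windows = _windowed(X, w, self.config.stride)
            for forest in self.forests_[w]:
                proba = forest.predict_proba(Xw)  # (n * n_windows, n_classes)
                # regroup to (n, n_windows * n_classes), window-major
                parts.append(
                    proba.reshape(n_windows, n, self.n_classes)
                    .transpose(1, 0, 2)
                    .reshape(n, n_windows * self.n_classes)
                )
        return np.concatenate(parts, axis=1)


def scanned_length(d: int, grain: GrainConfig, n_classes: int = 2) -> int:
    """Output length of multigrain scanning for a d-dimensional vector."""
    total = 0
    for w in grain.window_lengths:
        total += len(_window_starts(d, w, grain.stride)) * grain.n_scan_forests * n_classes
    return total


def multigrain_scan(
    features: np.ndarray, grain_config: GrainConfig, fitted_scanner: MultigrainScanner
) -> np.ndarray:
    """Transform feature vectors through fitted scanning forests."""
    if fitted_scanner.config is not grain_config and (
        fitted_scanner.config != grain_config
    ):
        raise ValueError("scanner was fitted with a different grain configuration")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    return fitted_scanner.transform(X)


@dataclass
class CascadeModel:
    """A fitted deep forest: scanner plus the kept cascade levels."""

    scanner: MultigrainScanner
    levels: list[list]
    classes: np.ndarray
    val_accuracy_per_level: list[float]
    d_in: int
    config: CascadeConfig

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _level_kinds(forests_per_level: int) -> list[str]:
    half = forests_per_level // 2
    return ["random"] * half + ["completely_random"] * half


def fit_cascade(
    X: np.ndarray,
    y: Sequence[int],
    grain_config: GrainConfig | None = None,
    cascade_config: CascadeConfig | None = None,
) -> CascadeModel:
    """Train the deep forest: scanning forests, then adaptively-grown levels.

    Training class vectors passed between levels are out-of-fold
    predictions from a stratified ``cv_folds``-fold split; the level's
    validation accuracy is the accuracy of the averaged out-of-fold class
    vectors.  The returned model is truncated to the depth with the best
    validation accuracy.
    """
    grain_config = grain_config or GrainConfig()
    cascade_config = cascade_config or CascadeConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if X.shape[0] < cascade_config.cv_folds:
        raise ValueError("need at least cv_folds samples")

    scanner = MultigrainScanner(grain_config, classes.size, cascade_config.seed).fit(X, y)
    Z = scanner.transform(X)

    levels: list[list] = []
    accs: list[float] = []
    kinds = _level_kinds(cascade_config.forests_per_level)
    aug = Z
    best_acc, best_depth, stall = -np.inf, 0, 0
    for level_idx in range(cascade_config.max_levels):
        oof_probas = []
        forests = []
        cv = StratifiedKFold(
            n_splits=cascade_config.cv_folds,
            shuffle=True,
            random_state=cascade_config.seed + 7919 * (level_idx + 1),
        )
        for fi, kind in enumerate(kinds):
            forest = _make_forest(
                kind,
                cascade_config.trees_per_forest,
                cascade_config.seed + 100 * (level_idx + 1) + fi,
            )
            oof = cross_val_predict(forest, aug, y, cv=cv, method="predict_proba")
            forest.fit(aug, y)
            oof_probas.append(oof)
            forests.append(forest)
        mean_oof = np.mean(oof_probas, axis=0)
        acc = float(np.mean(classes[np.argmax(mean_oof, axis=1)] == y))
        levels.append(forests)
        accs.append(acc)
        if acc > best_acc + cascade_config.improve_tol:
            best_acc, best_depth, stall = acc, level_idx + 1, 0
        else:
            stall += 1
            if stall >= cascade_config.patience:
                break
        aug = np.concatenate([Z] + oof_probas, axis=1)

    return CascadeModel(
        scanner=scanner,
        levels=levels[:best_depth],
        classes=classes,
        val_accuracy_per_level=accs[:best_depth],
        d_in=X.shape[1],
        config=cascade_config,
    )


def predict_proba(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities: rows sum to 1, class order fixed ascending
    (for seizure detection: [nonseizure, seizure])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d_in:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training dimension "
            f"{model.d_in}"
        )
    Z = model.scanner.transform(X)
    aug = Z
    probas = None
    for forests in model.levels:
        probas = [forest.predict_proba(aug) for forest in forests]
        aug = np.concatenate([Z] + probas, axis=1)
    assert probas is not None
    return np.mean(probas, axis=0)


def predict(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    proba = predict_proba(model, X)
    return model.classes[np.argmax(proba, axis=1)]
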