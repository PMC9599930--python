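"""Shared fixtures: the separable blob fixture for the classifier and one
full synthetic train/detect run reused by the pipeline and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from vmdforest import PipelineConfig, SeizureSpec, SynthConfig, generate_record
from vmdforest.deep_forest import CascadeConfig, GrainConfig, fit_cascade
from vmdforest.pipeline import evaluate_run, run_detector, train_detector


def make_blobs(seed: int, n: int = 200, shift: float = 3.0):
    """Two seeded 2-D Gaussian blobs, each coordinate shifted by 3 sigma,
    zero-padded to 6 features (the single-channel LECM dimension)."""
    rng = np.random.default_rng(seed)
    n2 = n // 2
    X = np.vstack([rng.normal(0.0, 1.0, (n2, 2)), rng.normal(shift, 1.0, (n2, 2))])
    X = np.hstack([X, np.zeros((n, 4))])
    y = np.array([0] * n2 + [1] * n2)
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def blob_data():
    Xtr, ytr = make_blobs(1)
    Xte, yte = make_blobs(2)
    return Xtr, ytr, Xte, yte


@pytest.fixture(scope="session")
def blob_model(blob_data):
    Xtr, ytr, _, _ = blob_data
    return fit_cascade(Xtr, ytr, GrainConfig(), CascadeConfig(seed=5))


@pytest.fixture(scope="session")
def e2e_run():
    """Train on one synthetic record, detect on a disjoint one.

    600-s single-channel records with one 60-s rhythmic seizure each,
    ictal/interictal amplitude ratio 5, 15 dB sensor SNR.
    """
    train_cfg = SynthConfig(
        n_channels=1, duration_s=600.0,
        seizures=(SeizureSpec(onset_s=200.0, duration_s=60.0),), seed=11,
    )
    test_cfg = SynthConfig(
        n_channels=1, duration_s=600.0,
        seizures=(SeizureSpec(onset_s=340.0, duration_s=60.0),), seed=12,
    )
    rec_tr, ann_tr = generate_record(train_cfg)
    rec_te, ann_te = generate_record(test_cfg)
    artifacts = train_detector(rec_tr, ann_tr, PipelineConfig().with_seed(1))
    result = run_detector(rec_te, artifacts)
    report = evaluate_run(result.decisions, ann_te)
    return {
        "train_record": rec_tr,
        "train_annotations": ann_tr,
        "test_record": rec_te,
        "test_annotations": ann_te,
        "artifacts": artifacts,
        "result": result,
        "report": report,
    }
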