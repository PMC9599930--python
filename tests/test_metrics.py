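"""Epoch and event metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest

from vmdforest.metrics import (
    ConfusionCounts,
    SeizureEvent,
    aggregate_event_metrics,
    confusion_counts,
    epoch_metrics,
    event_metrics,
    extract_events,
    gmean_percent,
)
from vmdforest.postprocess import collar_extend


def brute_force_epoch(labels, decisions):
    """Independent per-epoch counting oracle (plain loops)."""
    tp = fn = tn = fp = 0
    for y, d in zip(labels, decisions):
        if y == 1 and d == 1:
            tp += 1
        elif y == 1 and d == 0:
            fn += 1
        elif y == 0 and d == 0:
            tn += 1
        else:
            fp += 1
    sens = 100 * tp / (tp + fn)
    spec = 100 * tn / (tn + fp)
    acc = 100 * (tp + tn) / (tp + fn + tn + fp)
    return sens, spec, acc, (sens * spec) ** 0.5


def brute_force_events(detected, reference):
    """Independent interval-overlap oracle."""
    hits = 0
    for r0, r1 in reference:
        if any(min(d1, r1) > max(d0, r0) for d0, d1 in detected):
            hits += 1
    fps = sum(
        1 for d0, d1 in detected
        if not any(min(d1, r1) > max(d0, r0) for r0, r1 in reference)
    )
    return hits, fps


def random_intervals(rng, max_events=10, horizon=3600.0):
    k = rng.integers(0, max_events + 1)
    edges = np.sort(rng.uniform(0, horizon, 2 * k))
    return [(edges[2 * i], edges[2 * i + 1]) for i in range(k) if edges[2 * i] < edges[2 * i + 1]]


class TestEpochMetrics:
    def test_hand_computed_counts(self):
        m = epoch_metrics(ConfusionCounts(TP=3, FN=1, TN=90, FP=6))
        assert m.sensitivity == pytest.approx(75.00, abs=0.005)
        assert m.specificity == pytest.approx(93.75, abs=0.005)
        assert m.accuracy == pytest.approx(93.00, abs=0.005)
        assert m.g_mean == pytest.approx(83.85, abs=0.005)

    def test_low_sensitivity_patient_profile(self):
        # 52% sensitivity with 96.78% specificity gives G-mean 70.94
        m = epoch_metrics(ConfusionCounts(TP=13, FN=12, TN=4839, FP=161))
        assert m.sensitivity == pytest.approx(52.0)
        assert m.specificity == pytest.approx(96.78)
        assert round(m.g_mean, 2) == 70.94

    def test_perfect_classifier(self):
        m = epoch_metrics(ConfusionCounts(TP=10, FN=0, TN=90, FP=0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.g_mean) == (100, 100, 100, 100)

    def test_missing_class_errors_name_the_class(self):
        with pytest.raises(ValueError, match="seizure"):
            epoch_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=5))
        with pytest.raises(ValueError, match="nonseizure"):
            epoch_metrics(ConfusionCounts(TP=5, FN=5, TN=0, FP=0))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(4, 60)
            labels = rng.integers(0, 2, n)
            decisions = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            m = epoch_metrics(confusion_counts(labels, decisions))
            sens, spec, acc, gm = brute_force_epoch(labels, decisions)
            assert m.sensitivity == pytest.approx(sens)
            assert m.specificity == pytest.approx(spec)
            assert m.accuracy == pytest.approx(acc)
            assert m.g_mean == pytest.approx(gm)


class TestExtractEvents:
    def test_runs_become_events(self):
        events = extract_events([0, 1, 1, 0, 1], epoch_len_s=4.0)
        assert [(e.start_s, e.end_s) for e in events] == [(4.0, 12.0), (16.0, 20.0)]

    def test_all_zeros(self):
        assert extract_events([0, 0, 0]) == []

    def test_all_ones_single_event(self):
        events = extract_events([1, 1, 1], epoch_len_s=4.0)
        assert [(e.start_s, e.end_s) for e in events] == [(0.0, 12.0)]


class TestEventMetrics:
    def test_pooled_event_sensitivity_worked_example(self):
        # 54 reference events of which 51 are overlapped by detections
        reference = [SeizureEvent(60.0 * i, 60.0 * i + 30.0, "reference") for i in range(54)]
        detected = [SeizureEvent(60.0 * i + 10.0, 60.0 * i + 20.0) for i in range(51)]
        m = event_metrics(detected, reference, hours_evaluated=10.0)
        assert m.n_detected_true == 51
        assert m.event_sensitivity == pytest.approx(94.44, abs=0.005)
        assert m.n_false_positives == 0

    def test_no_detections(self):
        reference = [SeizureEvent(0.0, 10.0, "reference")]
        m = event_metrics([], reference, hours_evaluated=1.0)
        assert m.event_sensitivity == 0.0 and m.n_false_positives == 0

    def test_one_detection_covering_two_references(self):
        detected = [SeizureEvent(10.0, 20.0)]
        reference = [SeizureEvent(12.0, 15.0, "reference"), SeizureEvent(18.0, 25.0, "reference")]
        m = event_metrics(detected, reference, hours_evaluated=1.0)
        assert m.n_detected_true == 2 and m.n_false_positives == 0

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValueError):
            event_metrics([], [], hours_evaluated=0.0)

    def test_matches_brute_force_on_random_interval_sets(self):
        rng = np.random.default_rng(43)
        for _ in range(1000):
            det = random_intervals(rng)
            ref = random_intervals(rng)
            m = event_metrics(
                [SeizureEvent(a, b) for a, b in det],
                [SeizureEvent(a, b, "reference") for a, b in ref],
                hours_evaluated=1.0,
            )
            hits, fps = brute_force_events(det, ref)
            assert m.n_detected_true == hits
            assert m.n_false_positives == fps
            assert m.fdr_per_hour == pytest.approx(fps)


class TestAggregation:
    def test_gmean_percent(self):
        assert round(gmean_percent(52.0, 96.78), 2) == 70.94

    def test_event_aggregate_pools_events_and_averages_rates(self):
        rows = [
            event_metrics([SeizureEvent(0, 10)], [SeizureEvent(5, 15, "reference")], 2.0),
            event_metrics([SeizureEvent(100, 110)], [SeizureEvent(200, 210, "reference")], 1.0),
        ]
        agg = aggregate_event_metrics(rows)
        assert agg.n_reference == 2 and agg.n_detected_true == 1
        assert agg.event_sensitivity == pytest.approx(50.0)
        # unweighted mean of per-record rates: (0/2 + 1/1) / 2
        assert agg.fdr_per_hour == pytest.approx(0.5)


class TestCollarCrossCheck:
    def test_collar_never_hurts_event_sensitivity(self):
        rng = np.random.default_rng(44)
        for _ in range(50):
            n = int(rng.integers(10, 80))
            decisions = rng.integers(0, 2, n)
            labels = np.zeros(n, dtype=int)
            start = int(rng.integers(0, n - 3))
            labels[start : start + 3] = 1
            reference = extract_events(labels, epoch_len_s=4.0, source="reference")
            collar = int(rng.integers(0, 4))
            before = event_metrics(extract_events(decisions), reference, 1.0)
            after = event_metrics(
                extract_events(collar_extend(decisions, collar)), reference, 1.0
            )
            assert after.n_detected_true >= before.n_detected_true
            extended = collar_extend(decisions, collar).decisions
            fp_before = int(np.sum((decisions == 1) & (labels == 0)))
            fp_after = int(np.sum((extended == 1) & (labels == 0)))
            assert fp_after >= fp_before
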