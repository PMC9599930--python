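"""Variational mode decomposition: oracle checks, screening, diagnostics.

The two-tone oracle compares each recovered mode against an ideal
band-pass (spectral-mask) reconstruction of the corresponding pure tone,
which is independent of the ADMM solver under test.
"""

import numpy as np
import pytest

from vmdforest.vmd import (
    CenterFrequencyScanRow,
    TFMatrix,
    VMDConfig,
    build_tf_matrix,
    center_frequency_scan,
    correlation_select,
    decompose,
    is_monotone_increasing,
    mode_correlations,
    select_by_correlation,
)

FS = 256.0


def two_tone(fs=FS, seconds=4.0, f1=5.0, f2=40.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t), t


def spectral_mask_modes(x, fs, split_hz):
    """Independent oracle: ideal band-pass split of the spectrum."""
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    low = np.fft.irfft(np.where(freqs < split_hz, spectrum, 0), x.size)
    high = np.fft.irfft(np.where(freqs >= split_hz, spectrum, 0), x.size)
    return low, high


class TestDecompose:
    def test_zero_signal_gives_zero_modes(self):
        with pytest.warns(RuntimeWarning):  # constant input is also flagged
            result = decompose(np.zeros(512), FS, VMDConfig(K=3))
        np.testing.assert_allclose(result.modes, 0.0)
        np.testing.assert_allclose(result.residual, 0.0)

    def test_two_tone_center_frequencies_and_mode_shapes(self):
        x, t = two_tone()
        # multiplier enabled: exact-reconstruction enforcement is the right
        # setting for a clean band-limited oracle signal
        result = decompose(x, FS, VMDConfig(K=2, alpha=2000.0, tau=0.1))
        assert abs(result.center_freqs_hz[0] - 5.0) < 0.5
        assert abs(result.center_freqs_hz[1] - 40.0) < 0.5
        low, high = spectral_mask_modes(x, FS, split_hz=22.5)
        for mode, oracle in zip(result.modes, (low, high)):
            r = np.corrcoef(mode, oracle)[0, 1]
            assert abs(r) > 0.95

    def test_two_tone_reconstruction_residual(self):
        x, _ = two_tone()
        result = decompose(x, FS, VMDConfig(K=2, alpha=2000.0, tau=0.1))
        rel = np.linalg.norm(x - result.modes.sum(axis=0)) / np.linalg.norm(x)
        assert rel <= 0.05

    def test_residual_without_multiplier_is_boundary_ringing_only(self):
        # with tau=0 reconstruction is not enforced; the remaining error is
        # edge ringing from the mirror-extension seam and stays below 8%
        x, _ = two_tone()
        result = decompose(x, FS, VMDConfig(K=2, alpha=2000.0, tau=0.0))
        rel = np.linalg.norm(result.residual) / np.linalg.norm(x)
        assert rel <= 0.08
        interior = slice(64, -64)
        rel_interior = np.linalg.norm(result.residual[interior]) / np.linalg.norm(x[interior])
        assert rel_interior <= 0.02

    def test_mode_sum_plus_residual_is_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=700)
        result = decompose(x, FS, VMDConfig(K=4))
        np.testing.assert_allclose(result.modes.sum(axis=0) + result.residual, x,
                                   atol=1e-12)

    def test_center_frequencies_within_nyquist_and_sorted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1024)
        result = decompose(x, FS, VMDConfig(K=5))
        assert np.all(result.center_freqs_hz >= 0)
        assert np.all(result.center_freqs_hz <= FS / 2)
        assert np.all(np.diff(result.center_freqs_hz) >= 0)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=512)
        a = decompose(x, FS, VMDConfig(K=3))
        b = decompose(x, FS, VMDConfig(K=3))
        np.testing.assert_array_equal(a.modes, b.modes)
        np.testing.assert_array_equal(a.center_freqs_hz, b.center_freqs_hz)

    def test_pink_noise_lowest_mode_has_largest_variance(self):
        # 1/f background: low-frequency information is decomposed first and
        # carries the most power
        rng = np.random.default_rng(0)
        white = rng.standard_normal(1024)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(1024, d=1 / FS)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** -0.5
        pink = np.fft.irfft(spectrum * shaping, 1024)
        result = decompose(pink, FS, VMDConfig(K=5))
        assert int(np.argmax(result.modes.var(axis=1))) == 0

    def test_constant_signal_warns_and_surplus_modes_vanish(self):
        with pytest.warns(RuntimeWarning):
            result = decompose(np.full(256, 3.0), FS, VMDConfig(K=3))
        assert np.all(result.modes[1:].std(axis=1) < 1e-6)

    def test_non_finite_input_rejected(self):
        x = np.zeros(256)
        x[10] = np.nan
        with pytest.raises(ValueError):
            decompose(x, FS, VMDConfig(K=2))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.zeros(5), FS, VMDConfig(K=3))


class TestCorrelationSelect:
    @pytest.mark.parametrize(
        "correlations",
        [
            [0.7906, 0.7142, 0.3614, 0.1792, 0.0626],
            [0.8598, 0.5298, 0.3105, 0.1813, 0.0773],
        ],
        ids=["single-channel-set", "focal-montage-set"],
    )
    def test_reference_correlation_profiles_keep_first_three(self, correlations):
        assert select_by_correlation(correlations, threshold=0.3) == [0, 1, 2]

    def test_threshold_is_strict(self):
        assert select_by_correlation([0.5, 0.3, 0.30001], 0.3) == [0, 2]

    def test_modes_identical_to_signal_all_kept(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        result = decompose(x, FS, VMDConfig(K=2))
        fake = result
        fake.modes = np.vstack([x, x, x])
        assert correlation_select(fake, x) == [0, 1, 2]

    def test_zero_variance_signal_errors(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        result = decompose(x, FS, VMDConfig(K=2))
        with pytest.raises(ValueError):
            correlation_select(result, np.zeros(400))

    def test_end_to_end_selection_on_synthetic_epoch(self):
        t = np.arange(1024) / FS
        rng = np.random.default_rng(5)
        x = 5 * np.sin(2 * np.pi * 4 * t) + 0.3 * rng.normal(size=1024)
        result = decompose(x, FS, VMDConfig(K=5))
        selected = correlation_select(result, x, threshold=0.3)
        assert selected  # the dominant rhythm always survives screening
        best = int(np.argmax(mode_correlations(result, x)))
        assert best in selected


class TestCenterFrequencyScan:
    def test_pure_tone_single_mode(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 10 * t)
        rows = center_frequency_scan(x, FS, [1])
        assert rows[0].K == 1
        assert rows[0].center_freqs_hz[0] == pytest.approx(10.0, abs=0.5)

    def test_monotone_flagging(self):
        assert is_monotone_increasing([1, 5, 20])
        # over-decomposition signature: rises then falls
        assert not is_monotone_increasing([0.64, 13.34, 27.96, 46.44, 90.96, 8.88])

    def test_scan_reports_requested_mode_counts(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=512)
        rows = center_frequency_scan(x, FS, [1, 2, 3])
        assert [r.K for r in rows] == [1, 2, 3]
        assert all(len(r.center_freqs_hz) == r.K for r in rows)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            center_frequency_scan(np.zeros(128), FS, [])


class TestBuildTfMatrix:
    @staticmethod
    def _vmfset(n=694, K=5, seed=0):
        rng = np.random.default_rng(seed)
        return decompose(rng.normal(size=n), 173.6, VMDConfig(K=K))

    def test_single_channel_three_modes(self):
        tf = build_tf_matrix([self._vmfset()], [0, 1, 2])
        assert tf.values.shape == (694, 3)

    def test_three_channels_nine_columns(self):
        sets = [self._vmfset(seed=s) for s in range(3)]
        tf = build_tf_matrix(sets, [0, 1, 2])
        assert tf.m == 9
        # channel-major order: first three columns are channel 1's modes
        np.testing.assert_array_equal(tf.values[:, 0], sets[0].modes[0])
        np.testing.assert_array_equal(tf.values[:, 3], sets[1].modes[0])

    def test_no_selection_errors(self):
        with pytest.raises(ValueError):
            build_tf_matrix([self._vmfset()], [])

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            build_tf_matrix([self._vmfset(n=694), self._vmfset(n=512)], [0, 1])

    def test_single_column_matrix_rejected(self):
        with pytest.raises(ValueError):
            TFMatrix(np.zeros((10, 1)))
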