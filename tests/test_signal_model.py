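"""Recording IO, windowing, DC correction, and Kalman filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fmdetect as fm
from fmdetect.errors import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    ParseError,
)
from fmdetect.signal_model import (
    DEFAULT_SAMPLE_RATE,
    KalmanParams,
    Recording,
    kalman_filter,
    kalman_gains,
    moving_average,
    preprocess_window,
    remove_dc,
    segment_windows,
    window_array,
    window_length,
)


def write_recording_csv(path, rows, header="time_s,s1x,s1y,s1z,s2x,s2y,s2z"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestLoadRecording:
    def test_raw_counts_conversion_to_g(self, tmp_path):
        """A firmware count of 40,960,000 is 1.0 g after both gain divisions."""
        p = tmp_path / "rec.csv"
        write_recording_csv(p, [
            "0.00,40960000,0,0,0,0,0",
            "0.01,0,20480000,0,0,0,0",
            "0.02,0,0,0,0,0,0",
        ])
        rec = fm.load_recording(p, dialect="raw_counts")
        assert rec.channels[0, 0] == pytest.approx(1.0)
        assert rec.channels[1, 1] == pytest.approx(0.5)
        assert rec.sample_rate == pytest.approx(100.0)

    def test_g_units_values_unchanged(self, tmp_path):
        p = tmp_path / "rec.csv"
        write_recording_csv(p, ["0.00,0.05,0,0,0,0,0", "0.01,0.05,0,0,0,0,0"])
        rec = fm.load_recording(p, dialect="g_units")
        assert rec.channels[0, 0] == pytest.approx(0.05)

    def test_wrong_column_count_is_format_error(self, tmp_path):
        p = tmp_path / "rec.csv"
        p.write_text("time_s,s1x,s1y,s1z,s2x\n0,0,0,0,0\n")
        with pytest.raises(FormatError):
            fm.load_recording(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "rec.csv"
        write_recording_csv(p, ["0.00,0,0,0,0,0,0", "0.01,oops,0,0,0,0,0"])
        with pytest.raises(ParseError, match="line 3"):
            fm.load_recording(p)

    def test_annotation_sidecar_is_attached(self, tmp_path):
        p = tmp_path / "rec.csv"
        rows = [f"{k / 100:.2f},0,0,0,0,0,0" for k in range(300)]
        write_recording_csv(p, rows)
        a = tmp_path / "ann.csv"
        a.write_text("start_s,end_s,label\n1.0,2.0,FM_perceived\n")
        rec = fm.load_recording(p, annotation_path=a)
        assert len(rec.annotations) == 1
        assert rec.annotations[0].start_s == 1.0
        assert rec.annotations[0].label == "FM_perceived"

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = Recording(rng.normal(0, 0.01, (6, 512)),
                        annotations=[fm.EventInterval(1.0, 2.0)])
        fm.save_recording(rec, tmp_path / "r.csv", tmp_path / "a.csv")
        back = fm.load_recording(tmp_path / "r.csv", annotation_path=tmp_path / "a.csv")
        np.testing.assert_allclose(back.channels, rec.channels, atol=1e-6)
        assert back.annotations == rec.annotations


class TestSegmentWindows:
    @pytest.mark.parametrize("n_samples,expected", [
        (1000, 3), (256, 1), (360_000, 1406),
    ])
    def test_window_count_is_floor_of_samples_over_256(self, n_samples, expected):
        rec = Recording(np.zeros((6, n_samples)))
        windows = segment_windows(rec)
        assert all(len(per_axis) == expected for per_axis in windows)
        assert all(len(w.samples) == 256 for per_axis in windows for w in per_axis)

    def test_windows_partition_the_signal(self, rng):
        rec = Recording(rng.normal(size=(6, 1000)))
        windows = segment_windows(rec)
        for axis in range(6):
            rebuilt = np.concatenate([w.samples for w in windows[axis]])
            np.testing.assert_array_equal(rebuilt, rec.channels[axis, :768])
        assert [w.start_s for w in windows[0]] == [0.0, 2.56, 5.12]

    def test_too_short_recording_raises(self):
        with pytest.raises(DegenerateInputError):
            segment_windows(Recording(np.zeros((6, 100))))

    def test_window_array_matches_segmentation(self, rng):
        rec = Recording(rng.normal(size=(6, 600)))
        W = window_array(rec)
        windows = segment_windows(rec)
        np.testing.assert_array_equal(W[3, 1], windows[3][1].samples)

    def test_default_window_is_256_samples(self):
        assert window_length() == 256
        assert window_length(100.0, 2.56) == 256


class TestRemoveDc:
    def test_first_differences(self):
        np.testing.assert_array_equal(remove_dc([0.0, 1.0, 3.0, 6.0]), [0, 1, 2, 3])

    def test_constant_window_maps_to_zero(self):
        np.testing.assert_array_equal(remove_dc(np.full(256, 3.7)), np.zeros(256))

    @given(offset=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_constant_offset(self, offset):
        x = np.sin(np.linspace(0, 5, 64))
        np.testing.assert_allclose(remove_dc(x + offset), remove_dc(x), atol=1e-12)

    def test_cumsum_anchored_at_first_sample_reconstructs(self, rng):
        x = rng.normal(size=256)
        np.testing.assert_allclose(np.cumsum(remove_dc(x)) + x[0], x, atol=1e-12)


class TestKalmanFilter:
    def test_constant_input_is_fixed_point(self):
        p = KalmanParams(Q=0.0, R=1.0, x0=2.5)
        out = kalman_filter(np.full(64, 2.5), p)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_gains_match_closed_form_when_q_zero(self):
        """With A=H=1, Q=0 the error variance obeys 1/P_k = 1/P0 + k/R."""
        P0, R, n = 0.3, 2.0, 50
        K, P = kalman_gains(n, KalmanParams(Q=0.0, R=R, P0=P0))
        prev = P0
        for k in range(n):
            p_pred = prev
            assert K[k] == pytest.approx(p_pred / (p_pred + R), rel=1e-12)
            prev = 1.0 / (1.0 / P0 + (k + 1) / R)
            assert P[k] == pytest.approx(prev, rel=1e-10)

    def test_white_noise_variance_is_reduced(self):
        """Monte Carlo: filtering white noise shrinks its variance."""
        R = 1.0
        rng = np.random.default_rng(7)
        p = KalmanParams(Q=0.01, R=R, x0=0.0, P0=R)
        reduced = 0
        for _ in range(100):
            y = rng.normal(0.0, np.sqrt(R), 256)
            out = kalman_filter(y, p)
            reduced += np.var(out) < np.var(y)
        assert reduced == 100

    def test_huge_r_gives_pure_prediction(self, rng):
        y = rng.normal(size=128)
        out = kalman_filter(y, KalmanParams(Q=1e-6, R=1e12, x0=0.7, P0=1e-6))
        np.testing.assert_allclose(out, 0.7, atol=1e-3)

    def test_huge_q_tracks_measurements_over_h(self, rng):
        y = rng.normal(size=128)
        out = kalman_filter(y, KalmanParams(H=2.0, Q=1e12, R=1.0))
        np.testing.assert_allclose(out, y / 2.0, atol=1e-5)

    def test_error_variance_non_increasing_when_q_zero(self):
        _, P = kalman_gains(100, KalmanParams(Q=0.0, R=0.5, P0=1.0))
        assert np.all(np.diff(P) <= 1e-15)

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ParameterError):
            KalmanParams(R=0.0)

    def test_batch_matches_single(self, rng):
        Y = rng.normal(size=(4, 64))
        p = KalmanParams(Q=1e-3, R=0.1)
        batch = kalman_filter(Y, p)
        for i in range(4):
            np.testing.assert_array_equal(batch[i], kalman_filter(Y[i], p))


class TestPreprocessing:
    def test_respiration_band_is_suppressed(self):
        t = np.arange(256) / 100.0
        breath = 0.01 * np.sin(2 * np.pi * 0.3 * t + 1.0) + 0.15  # slow sine + DC
        out = preprocess_window(breath, KalmanParams(R=1e-5))
        assert np.max(np.abs(out)) < 0.005

    def test_fm_band_burst_is_preserved(self):
        t = np.arange(256) / 100.0
        burst = 0.03 * np.exp(-0.5 * ((t - 1.28) / 0.15) ** 2) * np.sin(2 * np.pi * 5 * t)
        out = preprocess_window(burst + 0.2, KalmanParams(R=1e-5))
        assert np.max(np.abs(out)) == pytest.approx(0.03, rel=0.2)

    def test_moving_average_of_constant_is_identity(self):
        np.testing.assert_allclose(moving_average(np.full(50, 1.3), 11), 1.3)

    def test_estimated_noise_matches_differenced_variance(self, rng):
        sigma = 0.003
        rec = Recording(rng.normal(0, sigma, (6, 2000)))
        r = fm.estimate_measurement_noise(rec)
        assert r == pytest.approx(2 * sigma**2, rel=0.2)
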