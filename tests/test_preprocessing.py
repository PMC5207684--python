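"""Preprocessing chain: smoothing, exclusion, gap filling, segmentation,
direction extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazetherm.panels import read_gaze_csv, write_gaze_csv
from gazetherm.preprocessing import (UnusableVideoError, exclude_subjects,
                                     interpolate_outliers,
                                     lowpass_triangular, segment,
                                     to_directions)

from conftest import make_panel


class TestLowpassTriangular:
    def test_constant_signal_is_preserved(self):
        panel = make_panel(np.full((1, 200), 37.0), np.full((1, 200), 11.0))
        out = lowpass_triangular(panel)
        np.testing.assert_allclose(out.x, 37.0, atol=1e-10)
        np.testing.assert_allclose(out.y, 11.0, atol=1e-10)

    def test_impulse_response_is_triangular(self):
        x = np.zeros((1, 101))
        x[0, 50] = 1.0
        out = lowpass_triangular(make_panel(x, x.copy()))
        resp = out.x[0]
        peak = int(np.argmax(resp))
        assert peak == 50
        left = resp[40:51]
        right = resp[50:61]
        assert np.all(np.diff(left) > 0)
        assert np.all(np.diff(right) < 0)
        np.testing.assert_allclose(resp, resp[::-1], atol=1e-12)
        assert resp[39] == 0.0 and resp[61] == 0.0

    def test_single_missing_sample_expands_to_21(self):
        """80 ms window at 250 Hz: +-40 ms = +-10 samples, 21 in total."""
        missing = np.zeros((1, 200), dtype=bool)
        missing[0, 100] = True
        panel = make_panel(np.random.default_rng(0).normal(size=(1, 200)),
                           np.zeros((1, 200)), missing=missing)
        out = lowpass_triangular(panel, window_ms=80)
        assert out.missing.sum() == 21
        assert out.missing[0, 90:111].all()

    def test_window_shorter_than_two_samples_rejected(self):
        panel = make_panel(np.zeros((1, 50)), np.zeros((1, 50)))
        with pytest.raises(ValueError):
            lowpass_triangular(panel, window_ms=1.0)

    def test_filter_is_zero_phase(self, rng):
        """Cross-correlation of a noisy sinusoid with its filtered version
        peaks at lag zero (no phase delay)."""
        t = np.arange(2000)
        x = np.sin(2 * np.pi * t / 80) + 0.3 * rng.standard_normal(t.size)
        out = lowpass_triangular(make_panel(x, np.zeros_like(x)))
        a = x - x.mean()
        b = out.x[0] - out.x[0].mean()
        lags = range(-15, 16)
        xc = [np.dot(a[30:-30], np.roll(b, k)[30:-30]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0


class TestExcludeSubjects:
    def _panel_with_missing(self, fracs):
        n = len(fracs)
        t = 1000
        missing = np.zeros((n, t), dtype=bool)
        for i, f in enumerate(fracs):
            missing[i, : int(round(f * t))] = True
        x = np.random.default_rng(1).normal(size=(n, t))
        return make_panel(x, x.copy(), missing=missing)

    def test_twenty_percent_rule_is_strict(self):
        panel = self._panel_with_missing([0.21, 0.0, 0.20])
        out = exclude_subjects(panel, 0.2)
        assert out.subject_ids == ["s01", "s02"]  # 20% exactly survives

    def test_zero_threshold_drops_any_missing(self):
        panel = self._panel_with_missing([0.001, 0.0])
        out = exclude_subjects(panel, 0.0)
        assert out.subject_ids == ["s01"]

    def test_all_excluded_raises(self):
        panel = self._panel_with_missing([0.5, 0.9])
        with pytest.raises(UnusableVideoError):
            exclude_subjects(panel, 0.2)


class TestInterpolateOutliers:
    def test_clean_panel_unchanged(self, rng):
        x = rng.normal(size=(4, 300)).cumsum(axis=1)
        panel = make_panel(x, x.copy())
        out = interpolate_outliers(panel, rank=2)
        np.testing.assert_array_equal(out.x, panel.x)

    def test_rank_one_gap_reconstruction(self, rng):
        """With one shared component across subjects, a held-out gap is
        reconstructed with correlation > 0.9 to the ground truth."""
        t = np.arange(2000)
        common = np.sin(2 * np.pi * t / 300) + 0.5 * np.sin(2 * np.pi * t / 71)
        loadings = np.array([1.0, 1.4, 0.8, 1.1, 0.7])
        x = loadings[:, None] * common[None, :]
        x_noisy = x + 0.02 * rng.standard_normal(x.shape)
        missing = np.zeros_like(x, dtype=bool)
        missing[0, 800:1000] = True
        panel = make_panel(x_noisy, x_noisy.copy(), missing=missing)
        out = interpolate_outliers(panel, rank=1)
        gap_true = x[0, 800:1000]
        gap_fill = out.x[0, 800:1000]
        assert np.corrcoef(gap_true, gap_fill)[0, 1] > 0.9
        # mask retained for correlation bookkeeping
        assert out.missing[0, 800:1000].all()

    def test_rank_must_be_below_subject_count(self):
        x = np.random.default_rng(0).normal(size=(3, 100))
        with pytest.raises(ValueError):
            interpolate_outliers(make_panel(x, x.copy()), rank=3)

    def test_entirely_missing_subject_escalates(self):
        x = np.random.default_rng(0).normal(size=(3, 100))
        missing = np.zeros_like(x, dtype=bool)
        missing[1] = True
        with pytest.raises(UnusableVideoError):
            interpolate_outliers(make_panel(x, x.copy(), missing=missing),
                                 rank=1)

    def test_artifact_spike_is_replaced(self, rng):
        t = np.arange(1500)
        common = np.sin(2 * np.pi * t / 200)
        x = np.vstack([common, common * 1.2, common * 0.9])
        x = x + 0.01 * rng.standard_normal(x.shape)
        x[0, 700] = 5000.0  # occlusion artifact
        panel = make_panel(x, x.copy())
        out = interpolate_outliers(panel, rank=1)
        assert abs(out.x[0, 700]) < 10.0


class TestSegment:
    def _panel_seconds(self, seconds, rate=250.0):
        n = int(seconds * rate)
        x = np.random.default_rng(0).normal(size=(2, n))
        return make_panel(x, x.copy(), rate_hz=rate)

    @pytest.mark.parametrize("seconds,expected", [(60, 2), (45, 1), (30, 1),
                                                  (90, 3)])
    def test_segment_counts(self, seconds, expected):
        assert len(segment(self._panel_seconds(seconds))) == expected

    def test_thirty_second_panel_is_identity(self):
        panel = self._panel_seconds(30)
        (seg,) = segment(panel)
        np.testing.assert_array_equal(seg.x, panel.x)

    def test_short_video_rejected(self):
        with pytest.raises(UnusableVideoError):
            segment(self._panel_seconds(10))

    def test_sample_conservation(self):
        panel = self._panel_seconds(75)
        segs = segment(panel)
        total = sum(s.n_samples for s in segs)
        assert total == (panel.n_samples // 7500) * 7500


class TestToDirections:
    def test_horizontal_motion(self):
        panel = make_panel([[0.0, 1.0, 2.0]], [[0.0, 0.0, 0.0]])
        dirs = to_directions(panel)
        assert dirs.valid[0, 1]
        np.testing.assert_allclose(dirs.sigma[0, 1], [1.0, 0.0])

    def test_diagonal_motion(self):
        panel = make_panel([[0.0, 1.0, 2.0]], [[0.0, 1.0, 2.0]])
        dirs = to_directions(panel)
        r2 = np.sqrt(2) / 2
        np.testing.assert_allclose(dirs.sigma[0, 1], [r2, r2])

    def test_fixation_has_no_direction(self):
        panel = make_panel([[5.0] * 10], [[3.0] * 10])
        dirs = to_directions(panel)
        assert not dirs.valid.any()

    def test_missing_stencil_invalidates(self):
        missing = np.zeros((1, 6), dtype=bool)
        missing[0, 2] = True
        panel = make_panel([np.arange(6.0)], [np.zeros(6)], missing=missing)
        dirs = to_directions(panel)
        assert not dirs.valid[0, 1] and not dirs.valid[0, 2] \
            and not dirs.valid[0, 3]
        assert dirs.valid[0, 4]

    @given(offset=st.floats(-1e4, 1e4), scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_and_scale_invariance(self, offset, scale):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(2, 50)).cumsum(axis=1)
        y = rng.normal(size=(2, 50)).cumsum(axis=1)
        base = to_directions(make_panel(x, y))
        moved = to_directions(make_panel(scale * x + offset,
                                         scale * y + offset))
        np.testing.assert_array_equal(base.valid, moved.valid)
        np.testing.assert_allclose(moved.sigma[base.valid],
                                   base.sigma[base.valid], atol=1e-9)


class TestGazeCsvRoundTrip:
    def test_round_trip_preserves_data_and_mask(self, tmp_path, rng):
        x = rng.normal(size=(3, 40)).cumsum(axis=1)
        missing = rng.random((3, 40)) < 0.2
        panel = make_panel(x, x * 2, missing=missing)
        path = tmp_path / "gaze.csv"
        write_gaze_csv(panel, path)
        back = read_gaze_csv(path)
        assert back.subject_ids == panel.subject_ids
        np.testing.assert_array_equal(back.missing, panel.missing)
        ok = ~panel.missing
        np.testing.assert_allclose(back.x[ok], panel.x[ok])
        np.testing.assert_allclose(back.y[ok], panel.y[ok])
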