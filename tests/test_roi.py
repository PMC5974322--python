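"""Registration, filtering, resampling, source extraction and trace math."""

import numpy as np
import pytest

from boutonscope import roi as roi_mod
from boutonscope import synthetic as syn
from boutonscope.benchmarks import recovery_scores
from boutonscope.core import ConfigError, GeometryError, MovieStack, ROISet


class TestRegisterRigid:
    def test_recovers_injected_jitter(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter
        # punctate scene (bright spots), as in bouton imaging
        frame = np.zeros((64, 64))
        idx = rng.integers(5, 59, (30, 2))
        frame[idx[:, 0], idx[:, 1]] = 100.0
        frame = gaussian_filter(frame, 1) + 10
        movie = MovieStack(data=np.repeat(frame[None], 8, axis=0),
                           fps=6.0, um_per_px=1.0)
        jittered, true_shifts = syn.apply_jitter(movie, max_px=3, seed=1)
        registered, shifts = roi_mod.register_rigid(jittered, reference=0)
        # corrections undo the injected shifts
        np.testing.assert_allclose(shifts, -true_shifts, atol=0.5)
        # interior pixels return close to the reference frame
        sl = (slice(None), slice(8, -8), slice(8, -8))
        before = np.abs(jittered.data[sl] - frame[8:-8, 8:-8]).mean()
        after = np.abs(registered.data[sl] - frame[8:-8, 8:-8]).mean()
        assert after < 0.2 * before

    def test_single_frame_is_identity(self):
        movie = MovieStack(data=np.random.default_rng(0).random((1, 16, 16)),
                           fps=1.0, um_per_px=1.0)
        out, shifts = roi_mod.register_rigid(movie)
        np.testing.assert_array_equal(out.data, movie.data)
        assert shifts.shape == (1, 2)


class TestSpatialFilter:
    def test_zero_sigma_identity(self, constant_movie):
        out = roi_mod.spatial_filter(constant_movie, 0.0)
        np.testing.assert_array_equal(out.data, constant_movie.data)

    def test_smoothing_preserves_mean_reduces_variance(self):
        rng = np.random.default_rng(1)
        movie = MovieStack(data=rng.random((3, 32, 32)) + 1, fps=6.0, um_per_px=0.5)
        out = roi_mod.spatial_filter(movie, sigma_um=1.0)
        assert out.data.mean() == pytest.approx(movie.data.mean(), rel=1e-3)
        assert out.data.var() < movie.data.var()

    def test_negative_sigma_rejected(self, constant_movie):
        with pytest.raises(ConfigError):
            roi_mod.spatial_filter(constant_movie, -1.0)


class TestTemporalResample:
    def test_block_means_hand_check(self):
        data = np.arange(25, dtype=float).reshape(25, 1, 1) + 1.0
        movie = MovieStack(data=data, fps=60.0, um_per_px=1.0)
        out = roi_mod.temporal_resample(movie, target_fps=6.0)
        # block = 10 frames; trailing 5 frames dropped
        assert out.n_frames == 2
        assert out.fps == pytest.approx(6.0)
        assert out.data[0, 0, 0] == pytest.approx(np.mean(np.arange(1, 11)))
        assert out.data[1, 0, 0] == pytest.approx(np.mean(np.arange(11, 21)))

    def test_upsampling_rejected(self, constant_movie):
        with pytest.raises(ConfigError):
            roi_mod.temporal_resample(constant_movie, target_fps=100.0)


class TestAR1Deconvolve:
    def test_recovers_event_times(self):
        fps, g_true = 6.0, 0.7
        events = np.zeros(300)
        events[[40, 120, 200]] = 5.0
        from scipy.signal import lfilter
        trace = lfilter([1.0], [1.0, -g_true], events) + 1.0
        rng = np.random.default_rng(2)
        trace = trace + rng.normal(0, 0.02, trace.shape)
        den, ev, g = roi_mod.ar1_deconvolve(trace)
        assert g == pytest.approx(g_true, abs=0.1)
        detected = np.flatnonzero(ev > 0)
        # every true event detected; small residual events may trail each
        # transient by a frame or two when the AR coefficient is imperfect
        assert {40, 120, 200} <= set(detected)
        assert all(min(abs(d - t) for t in (40, 120, 200)) <= 2 for d in detected)
        # the dominant mass sits on the true event frames
        assert ev[[40, 120, 200]].sum() > 0.9 * ev.sum()

    def test_flat_trace_yields_no_events(self):
        den, ev, g = roi_mod.ar1_deconvolve(np.full(50, 3.0))
        assert not ev.any()


class TestExtractRois:
    def test_constant_movie_gives_empty_set(self, constant_movie):
        rois = roi_mod.extract_rois(constant_movie)
        assert rois.n_rois == 0

    def test_recovers_boutons_on_small_scene(self, small_scene, small_movie):
        rois = roi_mod.extract_rois(small_movie, seed=0)
        scores = recovery_scores(small_scene, rois, um_per_px=1.0)
        assert scores["recall"] >= 0.8
        assert scores["precision"] >= 0.8
        assert rois.spatial.min() >= 0
        assert rois.events.min() >= 0
        assert rois.temporal.shape == (rois.n_rois, small_movie.n_frames)

    def test_determinism(self, small_movie):
        a = roi_mod.extract_rois(small_movie, seed=0)
        b = roi_mod.extract_rois(small_movie, seed=0)
        np.testing.assert_array_equal(a.spatial, b.spatial)
        np.testing.assert_array_equal(a.temporal, b.temporal)

    def test_hals_residual_non_increasing(self, small_movie):
        rois = roi_mod.extract_rois(small_movie, track_residuals=True)
        hist = np.asarray(rois.residual_history_)
        assert len(hist) > 1
        assert np.all(np.diff(hist) <= 1e-3 * hist[0])


def _toy_roiset():
    spatial = np.zeros((1, 4, 4))
    spatial[0, 1, 1] = 1.0
    spatial[0, 1, 2] = 0.5
    return ROISet(spatial=spatial, temporal=np.zeros((1, 3)),
                  events=np.zeros((1, 3)), background_spatial=np.zeros((4, 4)),
                  background_temporal=np.zeros(3), fps=6.0, um_per_px=1.0)


class TestTraces:
    def test_roi_fluorescence_hand_calc(self):
        rois = _toy_roiset()
        data = np.zeros((3, 4, 4))
        data[:, 1, 1] = [10.0, 20.0, 30.0]
        data[:, 1, 2] = [4.0, 6.0, 8.0]
        movie = MovieStack(data=data, fps=6.0, um_per_px=1.0)
        tr = roi_mod.roi_fluorescence(movie, rois)
        # weight-normalized average: (1*v11 + 0.5*v12) / (1 + 0.5)
        np.testing.assert_allclose(tr[0], [12 / 1.5, 23 / 1.5, 34 / 1.5])

    def test_roi_fluorescence_invariant_to_footprint_scale(self):
        rois = _toy_roiset()
        scaled = _toy_roiset()
        scaled.spatial = 37.0 * scaled.spatial
        data = np.random.default_rng(0).uniform(1, 10, (3, 4, 4))
        movie = MovieStack(data=data, fps=6.0, um_per_px=1.0)
        np.testing.assert_allclose(roi_mod.roi_fluorescence(movie, rois),
                                   roi_mod.roi_fluorescence(movie, scaled))

    def test_geometry_mismatch_raises(self, constant_movie):
        with pytest.raises(GeometryError):
            roi_mod.roi_fluorescence(constant_movie, _toy_roiset())

    def test_baseline_whole_mode_is_global_percentile(self):
        tr = np.arange(100.0)
        base = roi_mod.baseline_F(tr, fps=1.0, mode="whole")
        assert np.all(base == np.percentile(tr, 8))

    def test_baseline_sliding_tracks_slow_drift(self):
        t = np.arange(600)
        tr = 10.0 + 0.05 * t
        base = roi_mod.baseline_F(tr, fps=6.0, window_s=15.0)
        # windows span +-90 frames; the baseline follows the ramp
        assert base[-1] - base[0] > 0.8 * (tr[-1] - tr[0] - 0.05 * 180)
        # away from the (truncated) edges the baseline sits below the trace
        assert np.all(base[90:-90] <= tr[90:-90] + 1e-9)

    def test_baseline_invalid_mode(self):
        with pytest.raises(ConfigError):
            roi_mod.baseline_F(np.arange(10.0), 1.0, mode="median")

    def test_dff_algebra(self):
        tr = np.array([12.0, 10.0, 15.0])
        base = np.array([10.0, 10.0, 10.0])
        np.testing.assert_allclose(roi_mod.dff(tr, base), [0.2, 0.0, 0.5])

    def test_dff_nonpositive_baseline_raises_with_index(self):
        with pytest.raises(ConfigError, match="index 1"):
            roi_mod.dff(np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestAreaMetrics:
    def test_hand_area_and_diameter(self):
        # 4 um edge margin is ~19 px at 0.21 um/px, so use a roomy field
        spatial = np.zeros((1, 60, 60))
        spatial[0, 29:32, 29:32] = 1.0  # 9 pixels above threshold
        rois = ROISet(spatial=spatial, temporal=np.zeros((1, 2)),
                      events=np.zeros((1, 2)), background_spatial=np.zeros((60, 60)),
                      background_temporal=np.zeros(2), um_per_px=0.21)
        df = roi_mod.roi_area_metrics(rois)
        area = 9 * 0.21 ** 2
        assert df.loc[0, "area_um2"] == pytest.approx(area)
        assert df.loc[0, "diameter_um"] == pytest.approx(2 * np.sqrt(area / np.pi))
        assert not df.loc[0, "edge_excluded"]

    def test_edge_exclusion_flag(self):
        spatial = np.zeros((2, 30, 30))
        spatial[0, 1, 1] = 1.0    # within 4 um of the edge at 1 um/px
        spatial[1, 15, 15] = 1.0
        rois = ROISet(spatial=spatial, temporal=np.zeros((2, 2)),
                      events=np.zeros((2, 2)), background_spatial=np.zeros((30, 30)),
                      background_temporal=np.zeros(2), um_per_px=1.0)
        df = roi_mod.roi_area_metrics(rois)
        assert bool(df.loc[0, "edge_excluded"])
        assert not df.loc[1, "edge_excluded"]


class TestAverageImageAndRate:
    def test_single_delta_footprint(self):
        spatial = np.zeros((1, 21, 21))
        spatial[0, 10, 10] = 2.0
        rois = ROISet(spatial=spatial, temporal=np.zeros((1, 2)),
                      events=np.zeros((1, 2)), background_spatial=np.zeros((21, 21)),
                      background_temporal=np.zeros(2))
        img, profile = roi_mod.average_roi_image(rois, half_width_px=5)
        assert img.shape == (11, 11)
        assert img[5, 5] == pytest.approx(1.0)  # normalized footprint
        assert profile[5] == pytest.approx(1.0)
        assert img.sum() == pytest.approx(1.0)

    def test_no_rois_raises(self):
        rois = ROISet(spatial=np.zeros((0, 4, 4)), temporal=np.zeros((0, 2)),
                      events=np.zeros((0, 2)), background_spatial=np.zeros((4, 4)),
                      background_temporal=np.zeros(2))
        with pytest.raises(ConfigError):
            roi_mod.average_roi_image(rois)

    def test_spike_event_rate(self):
        ev = np.zeros(360)
        ev[[1, 50, 100, 150, 200, 300]] = 1.0
        assert roi_mod.spike_event_rate(ev, duration_s=60.0) == pytest.approx(6.0)
        with pytest.raises(ConfigError):
            roi_mod.spike_event_rate(ev, duration_s=0.0)
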