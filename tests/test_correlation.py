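"""Seed correlation maps, pairwise structure, peak density, plane overlap."""

import itertools

import numpy as np
import pytest

from boutonscope import correlation as corr
from boutonscope.core import ConfigError, GeometryError, MovieStack, ROISet


def _movie(data, fps=6.0, um_per_px=1.0):
    return MovieStack(data=np.asarray(data, dtype=float), fps=fps,
                      um_per_px=um_per_px)


class TestDownsample:
    def test_unit_factors_identity(self):
        rng = np.random.default_rng(0)
        mv = _movie(rng.random((20, 6, 6)))
        out = corr.downsample_for_corr(mv, 1, 1)
        np.testing.assert_allclose(out.data, mv.data)
        assert out.fps == mv.fps and out.um_per_px == mv.um_per_px

    def test_checkerboard_becomes_uniform(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        mv = _movie(np.stack([board, board]).astype(float))
        out = corr.downsample_for_corr(mv, 2, 1)
        np.testing.assert_allclose(out.data, 0.5)

    def test_frame_count_and_fps(self):
        mv = _movie(np.zeros((10_000, 4, 4)), fps=60.0)
        out = corr.downsample_for_corr(mv, 2, 10)
        assert out.n_frames == 1000
        assert out.fps == pytest.approx(6.0)
        assert out.um_per_px == pytest.approx(2.0)

    def test_trailing_partial_blocks_dropped(self):
        mv = _movie(np.arange(7, dtype=float)[:, None, None] * np.ones((7, 2, 2)))
        out = corr.downsample_for_corr(mv, 1, 3)
        np.testing.assert_allclose(out.data[:, 0, 0], [1.0, 4.0])

    def test_too_small_raises(self):
        with pytest.raises(ConfigError):
            corr.downsample_for_corr(_movie(np.zeros((2, 2, 2))), 4, 1)

    def test_bad_factor_raises(self):
        with pytest.raises(ConfigError):
            corr.downsample_for_corr(_movie(np.zeros((2, 2, 2))), 0, 1)


class TestSeedCorrelationMap:
    def _toy(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(100)
        data = np.zeros((100, 3, 3)) + 10.0  # intensities must stay positive
        data[:, 0, 0] = 10.0 + t
        data[:, 0, 1] = 2.0 * t + 15.0     # positively, perfectly correlated
        data[:, 0, 2] = 10.0 - t           # anti-correlated
        data[:, 1, 0] = 3.0                # constant -> correlation set to 0
        data[:, 1, 1] = 10.0 + rng.standard_normal(100)
        return _movie(data)

    def test_seed_pixel_is_one(self):
        cm = corr.seed_correlation_map(self._toy(), (0, 0))
        assert cm.values[0, 0] == pytest.approx(1.0)
        assert cm.seed_position == (0, 0)

    def test_affine_pixel_is_one(self):
        cm = corr.seed_correlation_map(self._toy(), (0, 0))
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pixel_is_minus_one(self):
        cm = corr.seed_correlation_map(self._toy(), (0, 0))
        assert cm.values[0, 2] == pytest.approx(-1.0)

    def test_constant_pixel_reports_zero(self):
        cm = corr.seed_correlation_map(self._toy(), (0, 0))
        assert cm.values[1, 0] == 0.0

    def test_positive_affine_invariance(self):
        mv = self._toy()
        cm0 = corr.seed_correlation_map(mv, (0, 0))
        cm1 = corr.seed_correlation_map(_movie(7.0 * mv.data + 11.0), (0, 0))
        np.testing.assert_allclose(cm1.values, cm0.values, atol=1e-12)

    def test_constant_seed_raises(self):
        with pytest.raises(ConfigError):
            corr.seed_correlation_map(self._toy(), (1, 0))

    def test_seed_outside_field_raises(self):
        with pytest.raises(GeometryError):
            corr.seed_correlation_map(self._toy(), (5, 0))


class TestPairwiseCorrelation:
    def test_identical_traces_all_ones(self):
        t = np.sin(np.linspace(0, 10, 50))
        mat, _, _ = corr.pairwise_correlation(np.tile(t, (3, 1)))
        np.testing.assert_allclose(mat, 1.0)

    def test_histogram_bin_width(self):
        rng = np.random.default_rng(2)
        mat, (counts, edges), _ = corr.pairwise_correlation(
            rng.standard_normal((5, 200)))
        assert edges[0] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diff(edges), 0.02)
        assert counts.sum() == 10  # 5 choose 2 upper-triangle values

    def test_cluster_order_groups_families(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(300)
        b = rng.standard_normal(300)
        traces = np.stack([
            a + 0.1 * rng.standard_normal(300),
            b + 0.1 * rng.standard_normal(300),
            a + 0.1 * rng.standard_normal(300),
            b + 0.1 * rng.standard_normal(300),
        ])
        _, _, order = corr.pairwise_correlation(traces)
        family = np.array([0, 1, 0, 1])[order]
        # members of the same family sit next to each other in leaf order
        assert family[0] == family[1] and family[2] == family[3]

    def test_single_trace_raises(self):
        with pytest.raises(ConfigError):
            corr.pairwise_correlation(np.ones((1, 10)))


class TestCorrelationDistanceSlope:
    def test_exact_linear_decay(self):
        rng = np.random.default_rng(4)
        centers = rng.uniform(0, 200, (8, 2))
        n = len(centers)
        mat = np.eye(n)
        for i, j in itertools.combinations(range(n), 2):
            d = np.linalg.norm(centers[i] - centers[j])
            mat[i, j] = mat[j, i] = 0.5 - 1e-4 * d
        slope = corr.correlation_distance_slope(mat, centers)
        assert slope == pytest.approx(-1e-4, rel=1e-9)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ConfigError):
            corr.correlation_distance_slope(np.eye(2), np.zeros((2, 2)))


class TestPeakDensity:
    def _bumpy_map(self, n_bumps, length_px=1000, um_per_px=1.0):
        vals = np.zeros((3, length_px))
        centers = (np.arange(n_bumps) + 0.5) * length_px / n_bumps
        x = np.arange(length_px)
        for c in centers:
            vals[1] += 0.8 * np.exp(-0.5 * ((x - c) / 3.0) ** 2)
        return corr.CorrelationMap(values=vals, seed_position=(1, 0),
                                   spatial_binning=1, temporal_binning=1,
                                   um_per_px=um_per_px)

    def test_counts_bumps_per_mm(self):
        cmap = self._bumpy_map(10)  # 10 bumps along a 1 mm row
        path = np.array([[0.5, 1.5], [999.5, 1.5]])  # um, center row
        density, positions = corr.peak_density_along_path(cmap, path)
        assert density == pytest.approx(10.0, rel=0.01)
        assert len(positions) == 10

    def test_flat_map_zero_density(self):
        cmap = corr.CorrelationMap(values=np.full((4, 100), 0.3),
                                   seed_position=(0, 0), spatial_binning=1,
                                   temporal_binning=1, um_per_px=1.0)
        density, positions = corr.peak_density_along_path(
            cmap, np.array([[0.0, 2.0], [99.0, 2.0]]))
        assert density == 0.0 and len(positions) == 0

    def test_degenerate_path_raises(self):
        cmap = self._bumpy_map(2)
        with pytest.raises(ConfigError):
            corr.peak_density_along_path(cmap, np.array([[1.0, 1.0]]))
        with pytest.raises(ConfigError):
            corr.peak_density_along_path(cmap, np.array([[1.0, 1.0], [1.0, 1.0]]))


def _roiset(footprints, traces, H=10, W=10):
    spatial = np.zeros((len(footprints), H, W))
    for i, px in enumerate(footprints):
        for r, c in px:
            spatial[i, r, c] = 1.0
    temporal = np.asarray(traces, dtype=float)
    T = temporal.shape[1]
    return ROISet(spatial=spatial, temporal=temporal,
                  events=np.zeros((len(footprints), T)),
                  background_spatial=np.zeros((H, W)),
                  background_temporal=np.zeros(T))


class TestPlaneOverlap:
    def test_identical_planes_fully_overlap(self):
        rng = np.random.default_rng(5)
        fp = [[(2, 2), (2, 3)], [(7, 7)]]
        # distinct, uncorrelated traces so the same-axon exclusion stays out
        rep = corr.plane_overlap_analysis([
            _roiset(fp, rng.standard_normal((2, 50))),
            _roiset(fp, rng.standard_normal((2, 50))),
        ])
        assert rep.n_overlapping == 4
        assert np.isinf(rep.overlap_ratio)
        np.testing.assert_allclose(rep.pairs["overlap_fraction"], 1.0)

    def test_disjoint_planes_zero_ratio(self):
        rng = np.random.default_rng(6)
        rep = corr.plane_overlap_analysis([
            _roiset([[(1, 1)]], rng.standard_normal((1, 50))),
            _roiset([[(8, 8)]], rng.standard_normal((1, 50))),
        ])
        assert rep.n_overlapping == 0
        assert rep.overlap_ratio == 0.0
        assert rep.pairs.empty

    def test_three_plane_toy_matches_brute_force(self):
        rng = np.random.default_rng(7)
        fps = [
            [[(1, 1), (1, 2), (2, 1)], [(5, 5)]],
            [[(1, 2), (2, 1), (2, 2)], [(8, 8)]],
            [[(5, 5), (5, 6)]],
        ]
        sets = [_roiset(f, rng.standard_normal((len(f), 80))) for f in fps]
        rep = corr.plane_overlap_analysis(sets, corr_exclusion=1.1)

        # brute force: shared pixels / smaller area, for every cross-plane pair
        expected = {}
        for pa, pb in itertools.combinations(range(3), 2):
            for ia, a in enumerate(fps[pa]):
                for ib, b in enumerate(fps[pb]):
                    shared = len(set(a) & set(b))
                    if shared:
                        expected[(pa, ia, pb, ib)] = shared / min(len(a), len(b))
        got = {(int(r.plane_a), int(r.roi_a), int(r.plane_b), int(r.roi_b)):
               r.overlap_fraction for r in rep.pairs.itertuples()}
        assert got == pytest.approx(expected)
        # overlapping: plane0/roi0 with plane1/roi0 share 2/3 > 0.5;
        # plane0/roi1 with plane2/roi0 share 1/1 > 0.5 -> 4 ROIs of 5
        assert rep.n_overlapping == 4
        assert rep.overlap_ratio == pytest.approx(4.0)

    def test_correlated_pair_excluded(self):
        t = np.sin(np.linspace(0, 12, 60))
        rep = corr.plane_overlap_analysis([
            _roiset([[(3, 3)]], t[None]),
            _roiset([[(3, 3)]], t[None]),
        ])
        assert rep.n_overlapping == 0
        assert len(rep.excluded_pairs) == 1
        assert rep.excluded_pairs.iloc[0]["temporal_corr"] == pytest.approx(1.0)

    def test_single_plane_raises(self):
        with pytest.raises(ConfigError):
            corr.plane_overlap_analysis([_roiset([[(0, 0)]], np.zeros((1, 5)))])
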