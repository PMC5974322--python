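"""Seed-based pixel-wise correlation maps, pairwise ROI correlation
structure, bouton density along arbors, and multi-plane ROI overlap.

Boutons of one axon share the parent neuron's spike train, so pixels on
the same arbor correlate strongly with a seed pixel on that arbor while
pixels of other axons do not; a correlation map therefore traces the
arbor as a beaded curve across the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.cluster import hierarchy
from scipy.ndimage import map_coordinates

from .core import ConfigError, GeometryError, MovieStack, ROISet

__all__ = [
    "CorrelationMap", "OverlapReport", "downsample_for_corr",
    "seed_correlation_map", "pairwise_correlation",
    "correlation_distance_slope", "peak_density_along_path",
    "plane_overlap_analysis",
]


@dataclass
class CorrelationMap:
    """Pearson correlation of every pixel's trace with one seed pixel."""

    values: np.ndarray                 # (H', W') in [-1, 1]
    seed_position: tuple[int, int]     # (row, col) in the binned frame
    spatial_binning: int
    temporal_binning: int
    um_per_px: float                   # after binning


@dataclass
class OverlapReport:
    """Cross-plane ROI overlap summary."""

    pairs: pd.DataFrame            # roi_a, roi_b, plane_a, plane_b, overlap_fraction
    excluded_pairs: pd.DataFrame   # overlapping pairs removed by temporal correlation
    overlap_ratio: float           # overlapping ROIs / non-overlapping ROIs
    n_rois_total: int
    n_overlapping: int


def downsample_for_corr(movie: MovieStack, spatial_factor: int = 2,
                        temporal_factor: int = 10) -> MovieStack:
    """Non-overlapping spatial and temporal mean-binning before mapping.

    2x2 spatial binning and 10-frame averaging turn 10,000 frames into
    1,000 time points per (binned) pixel; trailing partial blocks are
    dropped.
    """
    if spatial_factor < 1 or temporal_factor < 1:
        raise ConfigError("binning factors must be >= 1")
    data = np.asarray(movie.data, dtype=np.float32)
    T, H, W = data.shape
    Tb = T // temporal_factor
    Hb = H // spatial_factor
    Wb = W // spatial_factor
    if Tb < 1 or Hb < 1 or Wb < 1:
        raise ConfigError("movie too small for the requested binning")
    d = data[:Tb * temporal_factor, :Hb * spatial_factor, :Wb * spatial_factor]
    d = d.reshape(Tb, temporal_factor, Hb, spatial_factor, Wb, spatial_factor)
    d = d.mean(axis=(1, 3, 5))
    return MovieStack(data=d, fps=movie.fps / temporal_factor,
                      um_per_px=movie.um_per_px * spatial_factor)


def seed_correlation_map(movie: MovieStack, seed_pixel: tuple[int, int],
                         spatial_binning: int = 1, temporal_binning: int = 1
                         ) -> CorrelationMap:
    """Map of Pearson correlations between a seed pixel and all pixels.

    ``seed_pixel`` is (row, col) in the (already downsampled) movie.  The
    seed's own value is 1 by construction; a constant seed trace is an
    error.
    """
    data = np.asarray(movie.data, dtype=np.float64)
    T, H, W = data.shape
    r0, c0 = seed_pixel
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise GeometryError(f"seed {seed_pixel} outside field {H}x{W}")
    s = data[:, r0, c0]
    s = s - s.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ConfigError("seed trace is constant: correlation undefined")
    flat = data.reshape(T, -1)
    flat = flat - flat.mean(axis=0)
    denom = np.linalg.norm(flat, axis=0) * s_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (s @ flat) / denom
    vals[denom == 0] = 0.0
    vals = np.clip(vals.reshape(H, W), -1.0, 1.0)
    return CorrelationMap(values=vals, seed_position=(r0, c0),
                          spatial_binning=spatial_binning,
                          temporal_binning=temporal_binning,
                          um_per_px=movie.um_per_px)


def pairwise_correlation(traces: np.ndarray, hist_bin_width: float = 0.02
                         ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Pairwise Pearson matrix, histogram and hierarchical-cluster order.

    Returns (matrix, (hist_counts, bin_edges), leaf_order).  Clustering is
    agglomerative with distance ``1 - correlation`` and average linkage;
    the histogram covers the upper-triangle values with the given bin
    width.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ConfigError("need >= 2 ROI traces")
    mat = np.corrcoef(traces)
    mat = np.nan_to_num(mat, nan=0.0)
    np.fill_diagonal(mat, 1.0)
    iu = np.triu_indices_from(mat, k=1)
    vals = mat[iu]
    edges = np.arange(-1.0, 1.0 + hist_bin_width, hist_bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    dist = 1.0 - mat
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = dist[iu]
    Z = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(Z)
    return mat, (counts, edges), order


def correlation_distance_slope(matrix: np.ndarray, centers_um: np.ndarray
                               ) -> float:
    """OLS slope (per um) of pairwise correlation against pair distance."""
    matrix = np.asarray(matrix, dtype=float)
    centers = np.asarray(centers_um, dtype=float)
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    if len(iu[0]) < 3:
        raise ConfigError("need >= 3 ROI pairs")
    d = np.linalg.norm(centers[iu[0]] - centers[iu[1]], axis=1)
    c = matrix[iu]
    slope, _ = np.polyfit(d, c, 1)
    return float(slope)


def peak_density_along_path(cmap: CorrelationMap, path_um: np.ndarray,
                            min_prominence: float = 0.2,
                            sample_step_um: float | None = None
                            ) -> tuple[float, np.ndarray]:
    """Density (per mm) of correlation peaks along an axon-like path.

    Samples the map along the polyline (bilinear interpolation), detects
    local maxima by topographic prominence, and divides the peak count by
    the path length in millimetres.  Returns (density_per_mm, peak
    arc-length positions in um).
    """
    path = np.asarray(path_um, dtype=float)
    if path.ndim != 2 or len(path) < 2:
        raise ConfigError("path must be a polyline of >= 2 points (um)")
    seg = np.diff(path, axis=0)
    seglen = np.sqrt((seg ** 2).sum(axis=1))
    total = float(seglen.sum())
    if total <= 0:
        raise ConfigError("path length must be positive")
    if sample_step_um is None:
        sample_step_um = cmap.um_per_px / 2.0
    n_samples = max(int(total / sample_step_um) + 1, 2)
    arc = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    x = np.interp(arc, cum, path[:, 0])
    y = np.interp(arc, cum, path[:, 1])
    rows = y / cmap.um_per_px - 0.5
    cols = x / cmap.um_per_px - 0.5
    profile = map_coordinates(cmap.values, [rows, cols], order=1, mode="nearest")
    peaks, _ = sp_signal.find_peaks(profile, prominence=min_prominence)
    density = len(peaks) / (total / 1000.0)
    return float(density), arc[peaks]


def _roi_areas(rois: ROISet, area_threshold: float) -> np.ndarray:
    return rois.normalized_spatial() > area_threshold


def plane_overlap_analysis(roisets: list[ROISet], temporal: list[np.ndarray] | None = None,
                           area_threshold: float = 0.5,
                           overlap_threshold: float = 0.5,
                           corr_exclusion: float = 0.6,
                           denominator: str = "smaller") -> OverlapReport:
    """Cross-plane ROI overlap with same-axon exclusion.

    For every pair of ROIs on different planes, the overlap fraction is
    shared pixels divided by the pixel count of the reference ROI area
    (the smaller of the two by default).  Pairs whose temporal traces
    correlate above ``corr_exclusion`` are presumed to be boutons of the
    same axon (or the same bouton) and removed.  The overlap ratio is the
    number of overlapping ROIs divided by the number of all other ROIs.
    """
    if len(roisets) < 2:
        raise ConfigError("need >= 2 planes")
    if denominator not in ("smaller", "first"):
        raise ConfigError("denominator must be 'smaller' or 'first'")
    if temporal is None:
        temporal = [rs.temporal for rs in roisets]
    masks = [_roi_areas(rs, area_threshold) for rs in roisets]

    pair_rows, excl_rows = [], []
    overlapping: set[tuple[int, int]] = set()
    for pa in range(len(roisets)):
        for pb in range(pa + 1, len(roisets)):
            for ia in range(roisets[pa].n_rois):
                ma = masks[pa][ia]
                na = int(ma.sum())
                if na == 0:
                    continue
                for ib in range(roisets[pb].n_rois):
                    mb = masks[pb][ib]
                    nb = int(mb.sum())
                    if nb == 0:
                        continue
                    shared = int((ma & mb).sum())
                    if shared == 0:
                        continue
                    ref_n = min(na, nb) if denominator == "smaller" else na
                    frac = shared / ref_n
                    row = {"roi_a": ia, "roi_b": ib, "plane_a": pa,
                           "plane_b": pb, "overlap_fraction": frac}
                    if frac > overlap_threshold:
                        ta, tb = temporal[pa][ia], temporal[pb][ib]
                        if ta.std() > 0 and tb.std() > 0:
                            corr = float(np.corrcoef(ta, tb)[0, 1])
                        else:
                            corr = 0.0
                        row["temporal_corr"] = corr
                        if corr > corr_exclusion:
                            excl_rows.append(row)
                            continue
                        overlapping.add((pa, ia))
                        overlapping.add((pb, ib))
                    pair_rows.append(row)

    n_total = sum(rs.n_rois for rs in roisets)
    n_over = len(overlapping)
    n_non = n_total - n_over
    ratio = n_over / n_non if n_non > 0 else math.inf
    cols = ["roi_a", "roi_b", "plane_a", "plane_b", "overlap_fraction"]
    pairs_df = pd.DataFrame(pair_rows, columns=cols + ["temporal_corr"]) \
        if pair_rows else pd.DataFrame(columns=cols + ["temporal_corr"])
    excl_df = pd.DataFrame(excl_rows, columns=cols + ["temporal_corr"]) \
        if excl_rows else pd.DataFrame(columns=cols + ["temporal_corr"])
    return OverlapReport(pairs=pairs_df, excluded_pairs=excl_df,
                         overlap_ratio=float(ratio), n_rois_total=n_total,
                         n_overlapping=n_over)
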