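"""Neuropil decontamination of ROI traces.

Out-of-focus and surround ("neuropil") fluorescence mixes into each ROI's
trace.  The surround trace ``F_neuropil`` is the mean fluorescence of an
annulus within a fixed radius of the ROI support (the support itself is
excluded).  A robust linear regression of ``F_roi`` on ``F_neuropil`` —
computed after dropping time points where the ROI is transient-active —
gives a per-ROI contamination slope; the median slope across the field,
``r``, is applied uniformly: ``F_true = F_roi - r * F_neuropil``.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import ndimage

from .core import ConfigError, FitError, GeometryError, MovieStack, ROISet, TraceBundle
from .roi import baseline_F, dff, roi_fluorescence

__all__ = ["neuropil_trace", "contamination_factor", "decontaminate",
           "decontaminate_roiset"]


def neuropil_trace(movie: MovieStack, roi_spatial: np.ndarray,
                   radius_um: float = 2.0) -> np.ndarray:
    """Mean surround fluorescence per frame for one ROI.

    The surround is every pixel within ``radius_um`` of the ROI support
    but outside the support itself (an annulus, so the ROI's own signal
    does not regress on itself).
    """
    if radius_um <= 0:
        raise ConfigError("radius_um must be positive")
    support = np.asarray(roi_spatial) > 0
    if movie.data.shape[1:] != support.shape:
        raise GeometryError("movie and ROI geometry mismatch")
    radius_px = max(1, int(round(radius_um / movie.um_per_px)))
    dilated = ndimage.binary_dilation(support, iterations=radius_px)
    ring = dilated & ~support
    if not ring.any():
        raise GeometryError("ROI support fills the field: empty neuropil annulus")
    T = movie.n_frames
    return np.asarray(movie.data, dtype=float).reshape(T, -1)[:, ring.ravel()].mean(axis=1)


def contamination_factor(f_roi: np.ndarray, f_neuropil: np.ndarray,
                         sd_multiplier: float = 2.0,
                         min_points: int = 20) -> float:
    """Robust-regression slope of F_roi on F_neuropil.

    Time points where ``f_roi`` exceeds its mean plus ``sd_multiplier``
    standard deviations (calcium transients) are excluded; the slope of
    an iteratively re-weighted least-squares fit with bisquare weights
    (tuning constant 4.685) on the remaining points is returned.

    The slope is only meaningful when the surround trace actually varies:
    if the fitted slope is not distinguishable from zero (|slope| below
    twice its standard error) the contamination is unidentifiable and a
    FitError is raised rather than returning an arbitrary number.
    """
    f_roi = np.asarray(f_roi, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_roi.shape != f_neuropil.shape:
        raise ConfigError("f_roi and f_neuropil must be aligned")
    keep = f_roi <= f_roi.mean() + sd_multiplier * f_roi.std()
    if keep.sum() < min_points:
        raise FitError(f"only {int(keep.sum())} retained time points (< {min_points})")
    x, y = f_neuropil[keep], f_roi[keep]
    if x.std() == 0:
        raise FitError("degenerate neuropil trace (zero variance): slope undefined")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(slope) or not np.isfinite(se) or abs(slope) < 2.0 * se:
        raise FitError("contamination slope not distinguishable from zero")
    return slope


def decontaminate(f_roi: np.ndarray, f_neuropil: np.ndarray,
                  r_global: float) -> np.ndarray:
    """Subtract the field-wide contamination: F_true = F_roi - r * F_neuropil."""
    if not np.isfinite(r_global):
        raise ConfigError("r_global must be finite")
    return np.asarray(f_roi, dtype=float) - r_global * np.asarray(f_neuropil, dtype=float)


def decontaminate_roiset(movie: MovieStack, rois: ROISet,
                         radius_um: float = 2.0, sd_multiplier: float = 2.0,
                         baseline_mode: str = "sliding",
                         baseline_window_s: float = 15.0,
                         baseline_percentile: float = 8.0) -> TraceBundle:
    """Full trace chain for an ROISet: raw traces, surround traces, per-ROI
    contamination slopes, field-median r, decontaminated traces, baseline
    and dF/F.

    ``r`` is a mixing fraction in the model ``F_roi = F_true + r * F_np``,
    so only slopes inside [0, 1] enter the field median.  Slopes outside
    that range indicate the regression latched onto something other than
    surround contamination (most commonly the ROI's own point-spread skirt
    bleeding into the annulus when the surround itself barely fluctuates);
    if no ROI yields a physical slope, r is 0 and traces pass through
    unchanged.
    """
    f_roi = roi_fluorescence(movie, rois)
    f_np = np.stack([neuropil_trace(movie, rois.spatial[i], radius_um)
                     for i in range(rois.n_rois)])
    r_i = np.empty(rois.n_rois)
    for i in range(rois.n_rois):
        try:
            r_i[i] = contamination_factor(f_roi[i], f_np[i], sd_multiplier)
        except FitError:
            r_i[i] = np.nan
    valid = r_i[np.isfinite(r_i) & (r_i >= 0.0) & (r_i <= 1.0)]
    r_global = float(np.median(valid)) if len(valid) else 0.0
    f_true = np.stack([decontaminate(f_roi[i], f_np[i], r_global)
                       for i in range(rois.n_rois)])
    base = np.stack([baseline_F(f_true[i], movie.fps, baseline_mode,
                                baseline_window_s, baseline_percentile)
                     for i in range(rois.n_rois)])
    d = np.stack([dff(f_true[i], base[i]) for i in range(rois.n_rois)])
    return TraceBundle(f_roi=f_roi, f_neuropil=f_np, r_i=r_i, r_global=r_global,
                       f_true=f_true, baseline=base, dff=d)
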