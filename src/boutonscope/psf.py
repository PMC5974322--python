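"""Point-spread-function metrics: Gaussian FWHM fits of bead images and
signal-to-background quantification versus imaging depth.

The FWHM of a Gaussian profile is ``2 * sqrt(2 ln 2) * sigma``; lateral and
axial FWHMs of sub-resolution beads characterize the optical resolution of
the instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import FitError, GeometryError, MovieStack

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

__all__ = ["PSFFit", "FWHM_FACTOR", "fit_gaussian_fwhm", "bead_fwhm_3d",
           "signal_to_background", "sbr_depth_profile"]


@dataclass
class PSFFit:
    """Result of a 1-D Gaussian fit to an intensity profile."""

    center: float
    sigma: float
    amplitude: float
    offset: float
    residual_rms: float

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma


def _gauss(x: np.ndarray, offset: float, amplitude: float, center: float, sigma: float) -> np.ndarray:
    return offset + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma ** 2))


def fit_gaussian_fwhm(coords: np.ndarray, intensities: np.ndarray) -> PSFFit:
    """Least-squares Gaussian fit (with offset) to a 1-D intensity profile.

    Initialized from moments of the background-subtracted profile; raises
    :class:`FitError` on flat profiles or non-convergence rather than
    returning NaNs.
    """
    x = np.asarray(coords, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("coords and intensities must be matching 1-D arrays")
    if len(x) < 5:
        raise FitError(f"need >= 5 samples for a Gaussian fit, got {len(x)}")
    rng_y = y.max() - y.min()
    if rng_y <= 0:
        raise FitError("flat intensity profile: Gaussian fit undefined")

    # moment initialization on the offset-subtracted profile
    y0 = y - y.min()
    w = y0 / y0.sum()
    c0 = float((w * x).sum())
    var0 = float((w * (x - c0) ** 2).sum())
    sigma0 = math.sqrt(var0) if var0 > 0 else (x.max() - x.min()) / 6.0
    p0 = [y.min(), rng_y, c0, max(sigma0, 1e-6)]
    try:
        popt, _ = optimize.curve_fit(_gauss, x, y, p0=p0, xtol=1e-8, ftol=1e-8,
                                     maxfev=10_000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    offset, amplitude, center, sigma = popt
    sigma = abs(float(sigma))
    if sigma <= 0 or not np.isfinite(sigma):
        raise FitError("Gaussian fit collapsed to zero width")
    resid = y - _gauss(x, *popt)
    return PSFFit(center=float(center), sigma=sigma, amplitude=float(amplitude),
                  offset=float(offset), residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def _refine_center(stack: np.ndarray, approx: tuple[int, int, int],
                   radius: int = 5) -> tuple[float, float, float]:
    """Sub-voxel bead center: center of mass of the top 10% intensities
    inside a small box around the approximate position."""
    z0, r0, c0 = (int(round(v)) for v in approx)
    sl = tuple(slice(max(0, v - radius), v + radius + 1) for v in (z0, r0, c0))
    box = stack[sl]
    thr = np.quantile(box, 0.9)
    mask = box >= thr
    idx = np.argwhere(mask)
    wts = box[mask] - thr
    if wts.sum() <= 0:
        wts = np.ones(len(idx))
    com = (idx * wts[:, None]).sum(axis=0) / wts.sum()
    return tuple(com[d] + sl[d].start for d in range(3))


def bead_fwhm_3d(stack: MovieStack, bead_center: tuple[int, int, int],
                 z_step_um: float, depth_correction: float = 1.0,
                 margin_px: int = 4) -> tuple[PSFFit, PSFFit]:
    """Lateral (X) and axial (Z) FWHM fits through a bead in a Z-stack.

    ``bead_center`` is an approximate (z, row, col) voxel; the center is
    refined by center-of-mass of the top-decile intensities before the X
    and Z intensity lines through the maximum are fitted.  Z coordinates
    are pre-scaled by ``z_step_um * depth_correction`` (refractive-index
    mismatch correction).
    """
    data = np.asarray(stack.data, dtype=float)
    z, r, c = _refine_center(data, bead_center)
    zi, ri, ci = int(round(z)), int(round(r)), int(round(c))
    nz, nh, nw = data.shape
    if not (margin_px <= zi < nz - margin_px and margin_px <= ri < nh - margin_px
            and margin_px <= ci < nw - margin_px):
        raise GeometryError("bead too close to the stack edge for profile extraction")

    x_um = (np.arange(nw) + 0.5) * stack.um_per_px
    lateral = fit_gaussian_fwhm(x_um, data[zi, ri, :])
    z_um = np.arange(nz) * z_step_um * depth_correction
    axial = fit_gaussian_fwhm(z_um, data[:, ri, ci])
    return lateral, axial


def signal_to_background(image: np.ndarray, bead_center: tuple[int, int],
                         um_per_px: float, square_um: float = 30.0,
                         exclusion_diameter_um: float = 10.0) -> float:
    """Peak-to-surround ratio around an in-focus bead.

    Signal is the maximum intensity inside a ``square_um`` square centered
    on the bead; background is the mean intensity of that square excluding
    the central circle of ``exclusion_diameter_um``.
    """
    img = np.asarray(image, dtype=float)
    r0, c0 = bead_center
    half = int(round(square_um / 2.0 / um_per_px))
    if half < 1:
        raise GeometryError("square smaller than one pixel")
    rlo, rhi = r0 - half, r0 + half + 1
    clo, chi = c0 - half, c0 + half + 1
    if rlo < 0 or clo < 0 or rhi > img.shape[0] or chi > img.shape[1]:
        raise GeometryError("square does not fit inside the image")
    sq = img[rlo:rhi, clo:chi]
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dist_um = np.hypot(rr - r0, cc - c0) * um_per_px
    ring = sq[dist_um > exclusion_diameter_um / 2.0]
    if ring.size == 0:
        raise GeometryError("exclusion circle covers the whole square")
    bg = ring.mean()
    if bg <= 0:
        raise FitError("background mean <= 0: signal-to-background undefined")
    return float(sq.max() / bg)


def sbr_depth_profile(stack_a: MovieStack, stack_b: MovieStack,
                      bead_centers: list[tuple[int, int]],
                      depth_indices: list[int], z_step_um: float,
                      square_um: float = 30.0,
                      exclusion_diameter_um: float = 10.0) -> pd.DataFrame:
    """Per-depth signal-to-background summary of two imaging modes.

    For each depth plane, computes the SBR of every bead in both stacks,
    reports mean and SEM per mode, and compares the two modes with an
    exact two-sample rank-sum test.
    """
    if len(bead_centers) < 2:
        raise GeometryError("need >= 2 beads per depth for a rank comparison")
    rows = []
    for zi in depth_indices:
        vals = {}
        for label, stk in (("a", stack_a), ("b", stack_b)):
            if zi >= stk.n_frames:
                raise GeometryError(f"depth index {zi} outside stack ({stk.n_frames} planes)")
            sbrs = [signal_to_background(stk.data[zi], ctr, stk.um_per_px,
                                         square_um, exclusion_diameter_um)
                    for ctr in bead_centers]
            vals[label] = np.asarray(sbrs)
        if len(vals["a"]) == 0 or len(vals["b"]) == 0:
            raise GeometryError("empty SBR group")
        res = stats.mannwhitneyu(vals["a"], vals["b"], alternative="two-sided",
                                 method="exact")
        rows.append({
            "depth_um": zi * z_step_um,
            "mean_a": vals["a"].mean(), "sem_a": stats.sem(vals["a"]) if len(vals["a"]) > 1 else 0.0,
            "mean_b": vals["b"].mean(), "sem_b": stats.sem(vals["b"]) if len(vals["b"]) > 1 else 0.0,
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
        })
    return pd.DataFrame(rows)
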