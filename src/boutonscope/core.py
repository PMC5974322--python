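"""Core data containers shared across the analysis stages.

The package works on calcium-imaging movies of sparsely labelled axonal
arbors: a movie is a ``T x H x W`` intensity time series with physical
calibration (micrometres per pixel, frames per second).  Downstream stages
produce sets of regions of interest (boutons or somata), per-ROI trace
bundles, and pixel-noise model fits.  Synthetic scenes carry the ground
truth needed to score every stage without real recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np


class BoutonscopeError(Exception):
    """Base class for all package-specific failures."""


class ConfigError(BoutonscopeError):
    """Invalid configuration or calibration."""


class FitError(BoutonscopeError):
    """A model fit failed to converge or the data are degenerate."""


class GeometryError(BoutonscopeError):
    """A spatial precondition is violated (object outside field, empty mask...)."""


@dataclass
class MovieStack:
    """A ``T x H x W`` fluorescence time series with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Non-negative intensities in arbitrary units.
    fps : float
        Frame rate in frames per second.
    um_per_px : float
        Lateral pixel size at the sample, micrometres per pixel.
    depth_um : float, optional
        Axial position of the imaged plane.
    """

    data: np.ndarray
    fps: float
    um_per_px: float
    depth_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ConfigError(f"movie must be T x H x W with all dims >= 1, got shape {self.data.shape}")
        if not (self.fps > 0):
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if not (self.um_per_px > 0):
            raise ConfigError(f"um_per_px must be positive, got {self.um_per_px}")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("movie intensities must be finite")
        if np.any(self.data < 0):
            raise ConfigError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def with_data(self, data: np.ndarray, fps: float | None = None) -> "MovieStack":
        """Copy calibration onto a new data array (optionally a new frame rate)."""
        return MovieStack(data=data, fps=self.fps if fps is None else fps,
                          um_per_px=self.um_per_px, depth_um=self.depth_um)


@dataclass
class GroundTruth:
    """Ground-truth record of a synthetic axonal-arbor scene.

    Geometry is in micrometres.  ``arbors`` are polylines (one per parent
    axon), ``boutons`` lie on their parent polyline and fire a thinned copy
    of the parent spike train, emulating sub-unity release probability.
    """

    field_um: tuple[float, float]           # (width_x, height_y) in um
    fps: float
    arbors: list[np.ndarray]                # each (n_i, 2) xy um; or (n_i, 3) xyz
    boutons: np.ndarray                     # (M, 2) or (M, 3) um positions
    parent_ids: np.ndarray                  # (M,) int index into arbors
    release_prob: np.ndarray                # (M,) in [0, 1]
    spike_trains: np.ndarray                # (M, T) binary, at fps
    parent_trains: np.ndarray               # (n_axons, T) binary
    kernel_rise_s: float = 0.18
    kernel_decay_s: float = 1.8
    kernel_amplitude: float = 1.0
    bouton_brightness: np.ndarray | None = None  # per-bouton relative brightness
    baseline_map: np.ndarray | None = None  # filled at render time
    nr_used: float | None = None
    seed: int | None = None

    @property
    def n_boutons(self) -> int:
        return len(self.boutons)

    @property
    def n_frames(self) -> int:
        if self.spike_trains.ndim == 2 and self.spike_trains.shape[1]:
            return self.spike_trains.shape[1]
        return self.parent_trains.shape[1] if self.parent_trains.ndim == 2 else 0

    def to_json(self, path: str | Path) -> None:
        """Serialize the scene (arrays as nested lists) to a JSON sidecar."""
        rec = {
            "field_um": list(self.field_um),
            "fps": self.fps,
            "arbors": [a.tolist() for a in self.arbors],
            "boutons": np.asarray(self.boutons).tolist(),
            "parent_ids": np.asarray(self.parent_ids).tolist(),
            "release_prob": np.asarray(self.release_prob).tolist(),
            "spike_trains": np.asarray(self.spike_trains, dtype=int).tolist(),
            "parent_trains": np.asarray(self.parent_trains, dtype=int).tolist(),
            "kernel_rise_s": self.kernel_rise_s,
            "kernel_decay_s": self.kernel_decay_s,
            "kernel_amplitude": self.kernel_amplitude,
            "bouton_brightness": None if self.bouton_brightness is None else np.asarray(self.bouton_brightness).tolist(),
            "baseline_map": None if self.baseline_map is None else np.asarray(self.baseline_map).tolist(),
            "nr_used": self.nr_used,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(rec))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        rec = json.loads(Path(path).read_text())
        return cls(
            field_um=tuple(rec["field_um"]),
            fps=rec["fps"],
            arbors=[np.asarray(a, dtype=float) for a in rec["arbors"]],
            boutons=np.asarray(rec["boutons"], dtype=float),
            parent_ids=np.asarray(rec["parent_ids"], dtype=int),
            release_prob=np.asarray(rec["release_prob"], dtype=float),
            spike_trains=np.asarray(rec["spike_trains"], dtype=np.uint8),
            parent_trains=np.asarray(rec["parent_trains"], dtype=np.uint8),
            kernel_rise_s=rec["kernel_rise_s"],
            kernel_decay_s=rec["kernel_decay_s"],
            kernel_amplitude=rec["kernel_amplitude"],
            bouton_brightness=None if rec.get("bouton_brightness") is None
            else np.asarray(rec["bouton_brightness"], dtype=float),
            baseline_map=None if rec["baseline_map"] is None else np.asarray(rec["baseline_map"], dtype=float),
            nr_used=rec["nr_used"],
            seed=rec["seed"],
        )


@dataclass
class ROISet:
    """Spatial/temporal decomposition of a movie into ROIs plus background.

    ``spatial[i]`` is the non-negative footprint a_i (H x W), ``temporal[i]``
    the denoised calcium trace c_i, ``events[i]`` the non-negative deconvolved
    event series s_i.  A rank-1 background (b, f) absorbs the slowly varying
    field-wide fluorescence.
    """

    spatial: np.ndarray                 # (N, H, W) >= 0
    temporal: np.ndarray                # (N, T)
    events: np.ndarray                  # (N, T) >= 0
    background_spatial: np.ndarray      # (H, W)
    background_temporal: np.ndarray     # (T,)
    fps: float = 6.0
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.spatial = np.asarray(self.spatial, dtype=float)
        self.temporal = np.asarray(self.temporal, dtype=float)
        self.events = np.asarray(self.events, dtype=float)

    @property
    def n_rois(self) -> int:
        return self.spatial.shape[0]

    @property
    def centers(self) -> np.ndarray:
        """Argmax pixel (row, col) of each spatial component."""
        if self.n_rois == 0:
            return np.zeros((0, 2), dtype=int)
        flat = self.spatial.reshape(self.n_rois, -1)
        idx = np.argmax(flat, axis=1)
        return np.stack(np.unravel_index(idx, self.spatial.shape[1:]), axis=1)

    def normalized_spatial(self) -> np.ndarray:
        """Footprints rescaled so max(a_i) = 1."""
        peaks = self.spatial.reshape(self.n_rois, -1).max(axis=1)
        peaks = np.where(peaks > 0, peaks, 1.0)
        return self.spatial / peaks[:, None, None]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, spatial=self.spatial, temporal=self.temporal, events=self.events,
            background_spatial=self.background_spatial,
            background_temporal=self.background_temporal,
            fps=self.fps, um_per_px=self.um_per_px)

    @classmethod
    def load(cls, path: str | Path) -> "ROISet":
        with np.load(path) as z:
            return cls(spatial=z["spatial"], temporal=z["temporal"], events=z["events"],
                       background_spatial=z["background_spatial"],
                       background_temporal=z["background_temporal"],
                       fps=float(z["fps"]), um_per_px=float(z["um_per_px"]))


@dataclass
class TraceBundle:
    """Per-ROI traces through the decontamination and normalization chain."""

    f_roi: np.ndarray        # (N, T) raw ROI traces
    f_neuropil: np.ndarray   # (N, T) surround traces
    r_i: np.ndarray          # (N,) per-ROI contamination slopes
    r_global: float          # median slope applied field-wide
    f_true: np.ndarray       # (N, T) decontaminated traces
    baseline: np.ndarray     # (N, T) baseline F
    dff: np.ndarray          # (N, T) (f_true - baseline) / baseline


@dataclass
class NoiseModelFit:
    """Per-pixel gamma noise model summarized by the noise ratio NR.

    NR is the slope of per-pixel signal variance regressed on the per-pixel
    time-averaged signal; a mean-proportional variance is the signature of
    photon/camera noise on these sensors.
    """

    pixel_mean: np.ndarray          # (n,)
    pixel_variance: np.ndarray      # (n,)
    gamma_shape: np.ndarray | None  # (n,) fitted k per pixel (optional)
    gamma_scale: np.ndarray | None  # (n,) fitted theta per pixel (optional)
    nr: float
    intercept: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_mean)
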