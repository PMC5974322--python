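"""Deterministic arithmetic of the spinning-disk / camera imaging geometry.

Pure functions over an :class:`OpticsConfig`: maximum frame rate from disk
rotation, pinhole spacing projected to the focal plane, pixel size at the
sample, refractive-index depth correction, and raw data rates.  All
operations return full precision; rounding for display is the caller's
concern (see :func:`fmt`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import ConfigError

__all__ = [
    "OpticsConfig", "max_frame_rate", "focal_plane_spacing",
    "pixel_size_at_sample", "axial_depth_correction", "data_rate", "fmt",
]


@dataclass
class OpticsConfig:
    """Spinning-disk confocal geometry.

    ``scan_fraction`` is the fraction of one disk rotation needed to sweep
    the full field (1/3 for a disk whose pinhole pattern tiles the field
    three times per revolution).
    """

    total_magnification: float = 13.0
    disk_rpm: float = 10_000.0
    scan_fraction: float = 1.0 / 3.0
    pinhole_spacing_um_on_disk: float = 500.0
    fov_um: tuple[float, float] = (1106.0, 900.0)
    sensor_pixels: tuple[int, int] = (5310, 4320)
    n_immersion: float = 1.00
    n_specimen: float = 1.33

    def __post_init__(self) -> None:
        for name in ("total_magnification", "disk_rpm", "pinhole_spacing_um_on_disk",
                     "n_immersion", "n_specimen"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (0 < self.scan_fraction <= 1):
            raise ConfigError("scan_fraction must be in (0, 1]")
        if min(self.fov_um) <= 0 or min(self.sensor_pixels) < 1:
            raise ConfigError("fov and sensor dimensions must be positive")


def max_frame_rate(cfg: OpticsConfig) -> float:
    """Maximum frame rate (fps): one field per ``scan_fraction`` of a rotation."""
    return (cfg.disk_rpm / 60.0) / cfg.scan_fraction


def focal_plane_spacing(cfg: OpticsConfig) -> float:
    """Pinhole spacing on the disk demagnified to the focal plane (um)."""
    return cfg.pinhole_spacing_um_on_disk / cfg.total_magnification


def pixel_size_at_sample(fov_um: float, n_pixels: int) -> float:
    """Pixel size at the sample (um/px) along one axis."""
    if n_pixels < 1:
        raise ConfigError("n_pixels must be >= 1")
    if fov_um <= 0:
        raise ConfigError("fov_um must be positive")
    return fov_um / n_pixels


def axial_depth_correction(stage_displacement_um: float, cfg: OpticsConfig) -> float:
    """True focal displacement in the specimen for a given stage move.

    With an air objective focused into an aqueous specimen the focal plane
    moves ``n_specimen / n_immersion`` times the stage displacement.
    """
    if stage_displacement_um < 0:
        raise ConfigError("displacement must be >= 0")
    return stage_displacement_um * cfg.n_specimen / cfg.n_immersion


def data_rate(width_px: int, height_px: int, bytes_per_px: int, fps: float) -> float:
    """Raw acquisition rate in bytes per hour."""
    if min(width_px, height_px, bytes_per_px) <= 0 or fps <= 0:
        raise ConfigError("all data-rate inputs must be positive")
    return float(width_px) * height_px * bytes_per_px * fps * 3600.0


def fmt(value: float, decimals: int = 2) -> str:
    """Round for display the way optics tables are usually printed."""
    return f"{value:.{decimals}f}"
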