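"""Movie I/O, run configuration and the end-to-end pipeline driver.

Movies travel as multi-page TIFF (16-bit unsigned, one page per frame)
with the physical calibration supplied via config; internal computation
is floating point.  Every pipeline run writes a provenance record
(parameters, seed, package version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .core import ConfigError, MovieStack
from .neuropil import decontaminate_roiset
from .roi import extract_rois, register_rigid, spatial_filter, temporal_resample

log = logging.getLogger(__name__)

__all__ = ["read_movie", "write_movie", "RunConfig", "run_pipeline"]


def read_movie(path: str | Path, um_per_px: float, fps: float,
               depth_um: float | None = None) -> MovieStack:
    """Read a multi-page TIFF time series as a calibrated MovieStack."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input movie not found: {path}")
    if um_per_px is None or fps is None:
        raise ConfigError("um_per_px and fps calibration are required")
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise ConfigError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ConfigError(f"expected a T x H x W stack in {path}, got shape {data.shape}")
    return MovieStack(data=data.astype(np.float32), fps=fps, um_per_px=um_per_px,
                      depth_um=depth_um)


def write_movie(movie: MovieStack, path: str | Path, dtype=np.uint16) -> None:
    """Write a movie as multi-page TIFF (16-bit unsigned by default)."""
    data = np.asarray(movie.data)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.round(data), info.min, info.max).astype(dtype)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


@dataclass
class RunConfig:
    """Parameters of one end-to-end extraction run."""

    input_path: str
    um_per_px: float
    fps: float
    output_dir: str = "results"
    seed: int = 0
    register: bool = True
    filter_sigma_um: float = 0.2
    target_fps: float = 6.0
    max_components: int = 50
    min_snr: float = 5.0
    neuropil_radius_um: float = 2.0
    neuropil_sd: float = 2.0
    baseline_mode: str = "sliding"
    baseline_window_s: float = 15.0
    baseline_percentile: float = 8.0

    def __post_init__(self) -> None:
        for name in ("um_per_px", "fps", "target_fps", "neuropil_radius_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        rec = yaml.safe_load(Path(path).read_text())
        return cls(**rec)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Register -> filter -> resample -> extract -> traces -> neuropil.

    Writes the ROISet, traces (CSV) and a provenance record to the output
    directory; a failure in any stage aborts with the stage name in the
    log.  Returns a dict of the in-memory results.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    t0 = time.time()
    try:
        movie = read_movie(config.input_path, config.um_per_px, config.fps)
        if config.register and movie.n_frames >= 2:
            stage = "register"
            movie, shifts = register_rigid(movie)
        else:
            shifts = np.zeros((movie.n_frames, 2))
        stage = "filter"
        movie = spatial_filter(movie, config.filter_sigma_um)
        stage = "resample"
        movie = temporal_resample(movie, config.target_fps)
        stage = "extract"
        rois = extract_rois(movie, max_components=config.max_components,
                            min_snr=config.min_snr, seed=config.seed)
        stage = "traces"
        bundle = None
        if rois.n_rois:
            bundle = decontaminate_roiset(
                movie, rois, radius_um=config.neuropil_radius_um,
                sd_multiplier=config.neuropil_sd, baseline_mode=config.baseline_mode,
                baseline_window_s=config.baseline_window_s,
                baseline_percentile=config.baseline_percentile)
    except Exception as exc:
        log.error("pipeline failed at stage %r on %s: %s", stage,
                  config.input_path, exc)
        raise

    stage = "write"
    rois.save(out / "rois.npz")
    np.savetxt(out / "shifts.csv", shifts, delimiter=",", header="drow,dcol")
    if bundle is not None:
        import pandas as pd
        pd.DataFrame(bundle.dff.T).to_csv(out / "dff.csv", index=False)
        pd.DataFrame(bundle.f_roi.T).to_csv(out / "f_roi.csv", index=False)
    provenance = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "n_rois": rois.n_rois,
        "elapsed_s": time.time() - t0,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {"movie": movie, "rois": rois, "bundle": bundle, "shifts": shifts,
            "provenance": provenance}
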