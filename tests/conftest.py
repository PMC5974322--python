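import numpy as np
import pytest

from boutonscope import MovieStack
from boutonscope import synthetic as syn
from boutonscope import roi as roi_mod


@pytest.fixture(scope="session")
def small_scene():
    """A small noiseless-friendly scene reused across modules."""
    return syn.generate_scene((96.0, 96.0), n_axons=2, bouton_density_per_mm=110.0,
                              event_rate_per_min=40.0, duration_s=30.0, fps=60.0,
                              seed=1)


@pytest.fixture(scope="session")
def small_movie(small_scene):
    """Rendered movie at modest noise, resampled to 6 Hz for extraction."""
    mv = syn.render_movie(small_scene, um_per_px=1.0, psf_fwhm_um=1.5,
                          nr=0.5, seed=2, baseline=20.0, bouton_amp=30.0)
    return roi_mod.temporal_resample(mv, 6.0)


@pytest.fixture()
def constant_movie():
    return MovieStack(data=np.full((30, 8, 8), 7.0), fps=6.0, um_per_px=1.0)


@pytest.fixture(scope="session")
def benchmark_truth():
    from boutonscope.benchmarks import twenty_bouton_scene
    return twenty_bouton_scene(seed=7)


@pytest.fixture(scope="session")
def benchmark_movie(benchmark_truth):
    """The 256 x 256 um, 20-bouton extraction benchmark at NR 0.5."""
    mv = syn.render_movie(benchmark_truth, um_per_px=1.0, psf_fwhm_um=1.5,
                          nr=0.5, seed=8, baseline=20.0, bouton_amp=30.0)
    return roi_mod.temporal_resample(mv, 6.0)
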