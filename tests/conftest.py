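import numpy as np
import pytest
from scipy import ndimage as ndi

from sbfdetect import (FilterParams, NMSParams, SceneSpec, detect_cells,
                       generate_benchmark, generate_brightfield_scene)


@pytest.fixture(scope="session")
def small_params() -> FilterParams:
    """Band geometry scaled for 64x64 test images."""
    return FilterParams(r_min=3, r_max=10, n_lines=16, band_width=3)


@pytest.fixture(scope="session")
def smooth_images():
    """Reproducible batch of smooth random 64x64 images."""
    rng = np.random.default_rng(2024)
    return [ndi.gaussian_filter(rng.random((64, 64)), 1.5) for _ in range(20)]


def single_ring(radius: float, noise: float = 0.0, seed: int = 5,
                illumination: float = 0.0) -> "SyntheticScene":
    return generate_brightfield_scene(SceneSpec(
        height=128, width=128, n_cells=1, radius_range=(radius, radius),
        noise_sigma=noise, illumination_gradient=illumination, seed=seed))


@pytest.fixture(scope="session")
def ring16_clean():
    """Noise-free single ring cell of radius 16."""
    return single_ring(16.0)


@pytest.fixture(scope="session")
def benchmark42():
    """The default 15-image bright-field benchmark, seed 42."""
    return generate_benchmark(15, SceneSpec(), seed=42)


@pytest.fixture(scope="session")
def benchmark42_tsbf_counts(benchmark42):
    """TSBF pipeline counts per benchmark scene (default parameters)."""
    return [detect_cells(s.image).count for s in benchmark42]
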