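import numpy as np
import pytest

from rsaseg import PhantomSpec, VoxelVolume, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def clean_tooth():
    """Noise-free two-part tooth phantom with its analytic truth."""
    return generate(PhantomSpec(noise_sd=0.0))


def random_volume(rng, max_side=9):
    """Small random 8-bit volume for round-trip and property tests."""
    nz = int(rng.integers(1, 5))
    ny = int(rng.integers(3, max_side))
    nx = int(rng.integers(3, max_side))
    return VoxelVolume(
        rng.integers(0, 256, size=(nz, ny, nx), dtype=np.uint8),
        pixel_size_mm=float(rng.uniform(0.1, 1.0)),
        slice_spacing_mm=float(rng.uniform(0.1, 1.0)),
    )
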