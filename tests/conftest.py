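import numpy as np
import pytest

from cryopick.io import Micrograph
from cryopick.synthetic import SceneSpec, generate_scene


def rasterize_disk(shape, center, radius):
    """Boolean disk mask: pixel centers within `radius` of `center`."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


def rasterize_square(shape, top_left, side):
    mask = np.zeros(shape, dtype=bool)
    t, l = top_left
    mask[t:t + side, l:l + side] = True
    return mask


@pytest.fixture
def dim_disk_micrograph():
    """Low-contrast dark disks on a noisy bright background, with truth."""
    spec = SceneSpec(height=256, width=256, n_circles=6,
                     radius_range=(10, 12), background_level=0.6,
                     particle_contrast=0.3, noise_sigma=0.1,
                     min_separation=8.0, seed=42)
    return generate_scene(spec)


@pytest.fixture
def noise_micrograph():
    """Pure-background scene: no particles at all."""
    rng = np.random.default_rng(7)
    pixels = np.clip(rng.normal(0.6, 0.05, size=(128, 128)), 0, 1)
    return Micrograph(pixels=pixels, value_range=(0.0, 1.0),
                      source_id="background-only")


@pytest.fixture
def ramp_micrograph():
    """A smooth intensity ramp of 1000+ distinct values in [0, 1]."""
    vals = np.linspace(0.0, 1.0, 1000)
    return Micrograph(pixels=np.tile(vals, (40, 1)))
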