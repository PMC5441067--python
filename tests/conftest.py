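import numpy as np
import pytest

from musclefat import GrayImage, PixelGeometry, PhantomSpec


@pytest.fixture
def geom_1mm():
    return PixelGeometry(1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def random_image(rng):
    """A 64x64 8-bit image with a bright blob on a noisy dark background."""
    pix = rng.integers(0, 120, size=(64, 64))
    pix[20:44, 20:44] += 100
    return GrayImage(np.clip(pix, 0, 255).astype(np.uint8), levels=256)


@pytest.fixture
def easy_phantom_spec():
    """Well-separated classes, no noise, no bias: recovery should be exact."""
    return PhantomSpec(
        muscle_mean=0.25,
        fat_mean=0.75,
        noise_sd=0.0,
        bias_amplitude=0.0,
        target_fat_fraction=0.5,
        seed=11,
    )
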