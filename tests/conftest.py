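import numpy as np
import pytest

from roscope import SceneParams


@pytest.fixture
def small_scene() -> SceneParams:
    """A scaled-down acquisition used throughout the tests: same optics and
    noise model as the defaults, smaller frame so suites stay fast."""
    return SceneParams(image_size_px=128, n_slices=8, cell_radius_um=(6.0, 9.0),
                       puncta_rate=30.0)


@pytest.fixture
def clean_scene() -> SceneParams:
    """Noise-free small scene: no background, no shot noise, no read noise."""
    return SceneParams(image_size_px=128, n_slices=8, cell_radius_um=(6.0, 9.0),
                       puncta_rate=30.0, background_level=0.0,
                       read_noise_sigma=0.0, shot_noise=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
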