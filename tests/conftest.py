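import numpy as np
import pytest

from gistrad import SyntheticParams, TextureEffect, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    return SyntheticParams(n_images=20, image_shape=(96, 96), seed=7)


@pytest.fixture
def sample_image(small_params, rng):
    return generate_image(
        small_params, "Normal", 60.0, rng, image_id="img0", laterality="L"
    )


def random_roi(rng, shape=(16, 16), lo=0, hi=256):
    """Random image with a random (but non-trivial) ROI mask."""
    pixels = rng.integers(lo, hi, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return pixels, mask


@pytest.fixture
def zero_effect_params():
    return SyntheticParams(
        n_images=20,
        image_shape=(96, 96),
        texture_effect=TextureEffect.zero(),
        seed=3,
    )
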