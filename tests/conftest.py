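import numpy as np
import pytest

from isletquant import IsletImageParams, generate_islet_image


@pytest.fixture()
def separable_scene():
    """One small zero-noise, zero-bleed-through section with ground truth."""
    params = IsletImageParams(
        image_size_px=(384, 384),
        n_islets=3,
        diameter_median_um=60.0,
        noise_sigma=0.0,
        bleedthrough_alpha=0.0,
        seed=7,
    )
    return generate_islet_image(params)


@pytest.fixture()
def default_scene():
    """One section at the generator's default optical conditions."""
    return generate_islet_image(IsletImageParams(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
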