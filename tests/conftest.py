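import numpy as np
import pytest

from seedfc import Bold4D, SimScene, Region, default_scene, generate_participants


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_affine():
    aff = np.eye(4)
    aff[:3, :3] *= 3.0
    return aff


@pytest.fixture
def tiny_bold(rng, tiny_affine):
    """A 6x6x6 random BOLD image, 80 volumes, TR 2 s."""
    data = rng.standard_normal((6, 6, 6, 80))
    return Bold4D(data, tiny_affine, tr=2.0)


@pytest.fixture
def small_scene():
    """A 16^3 single-network scene kept cheap for unit tests."""
    return default_scene(("DMN",), grid_shape=(16, 16, 16), rng_seed=99)


@pytest.fixture
def small_table():
    return generate_participants((3, 3, 3), rng_seed=99)
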