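import numpy as np
import pytest

from lashgan.phantom import default_configs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_configs():
    """Phantom/eyelash configurations at the 64x64 desk scale."""
    return default_configs(64)


@pytest.fixture(scope="session")
def small_phantom_cfg(desk_configs):
    return desk_configs[0]


@pytest.fixture(scope="session")
def small_eyelash_cfg(desk_configs):
    return desk_configs[1]


@pytest.fixture
def random_image_pair(rng):
    a = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    b = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    return a, b
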