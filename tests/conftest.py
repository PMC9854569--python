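import numpy as np
import pytest

from spcnet.synth import GeneratorConfig, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gen_config():
    """Generator settings scaled for fast tests: 64x64, 3-6 small cells."""
    return GeneratorConfig(image_size=(64, 64), radius_range=(5.0, 12.0), cells_per_image=(3, 6))


@pytest.fixture(scope="session")
def small_dataset(small_gen_config):
    """Twenty seeded 64x64 image/label pairs shared across tests."""
    rng = np.random.default_rng(7)
    return [generate_image(rng, small_gen_config) for _ in range(20)]


@pytest.fixture(scope="session")
def one_pair(small_dataset):
    return small_dataset[0]
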