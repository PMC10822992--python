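import numpy as np
import pytest

from fundusvit import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_synth_config():
    """Desk-scale generator settings used across detector tests."""
    return SyntheticConfig(image_size=64, od_radius_range=(10.0, 18.0))


@pytest.fixture(scope="session")
def desk_samples(desk_synth_config):
    """200 small synthetic fundus samples, shared read-only across tests."""
    return generate_dataset(desk_synth_config, n=200, seed=11)
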