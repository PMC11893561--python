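import numpy as np
import pytest

from aamm import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_gen_config():
    """Low-dimensional generator for fast unit tests."""
    return GeneratorConfig(
        latent_dim=4,
        n_components=2,
        modality_dims=(12, 20, 8),
        bag_size_range=(5, 12),
        seed=123,
    )


SMALL_DIMS = {"p": 12, "c": 20, "t": 8, "r": 12}


@pytest.fixture(scope="session")
def small_dataset(small_gen_config):
    return generate_dataset(24, (0.5, 0.5), small_gen_config, seed=5)
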