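import numpy as np
import pytest

from cycleda import (NetShapeConfig, TrainConfig, default_benchmark_config,
                     generate_dataset)


@pytest.fixture(scope="session")
def tiny_net():
    """Smallest sensible network config; keeps unit tests fast."""
    return NetShapeConfig(image_side=32, base_filters=8, max_filters=32,
                          latent_channels=32, fc_width=64)


@pytest.fixture(scope="session")
def tiny_pair():
    """A small two-domain dataset on the benchmark's shift settings."""
    return generate_dataset(default_benchmark_config(seed=7, n_per_domain=64))


@pytest.fixture
def quick_cfg():
    return TrainConfig(epochs=1, batch_size=16, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
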