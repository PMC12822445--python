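import numpy as np
import pytest

from cpmp.model import ModelConfig, init_params
from cpmp.synthetic import simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return ModelConfig(
        input_dim=8, embed_dim=16, n_heads=2, ff_hidden_dim=24, n_agents=3
    )


@pytest.fixture
def small_params(small_config):
    return init_params(small_config, seed=7)


@pytest.fixture
def small_cohort():
    """Six labeled bags of 12 tiles x 8 channels with a strong planted signal."""
    return simulate_cohort(
        n_patients=6, tiles_per_slide=12, n_channels=8,
        signal_strength=3.0, signal_fraction=0.25, seed=42,
    )
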