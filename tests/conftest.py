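import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from codroplet.features import generate_cohort
from codroplet.network import ModelConfig, init_params


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Small dimensions suitable for nested-loop oracle comparison."""
    return ModelConfig(c_n=8, c_e=4, n_head=2, n_layers=1)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_params(tiny_config, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten short proteins in two latent clusters, noise-free."""
    return generate_cohort(10, length=(5, 7), n_clusters=2, noise_sd=0.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
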