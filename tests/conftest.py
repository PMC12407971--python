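import numpy as np
import pytest

from jansenrit import ModelConfig, SimulationProtocol
from jansenrit.connectome import synthetic_connectome


@pytest.fixture(scope="session")
def small_connectome():
    """Deterministic 8-region modular connectome used by network tests."""
    return synthetic_connectome(8, seed=0)


@pytest.fixture()
def short_protocol():
    """Cheap protocol for unit tests (10 s retained at 200 Hz)."""
    return SimulationProtocol(t_sim=16.0, t_discard=6.0, out_fs=200.0)


@pytest.fixture()
def base_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
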