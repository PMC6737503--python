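import numpy as np
import pytest

from ftsts.network import NetworkParams
from ftsts.plasticity import make_rule
from ftsts.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table_params():
    """Published-table network parameters at a tiny size for unit tests."""
    return NetworkParams(
        n_e=24, n_i=8, epsilon={"IE": 0.5, "EI": 0.5},
        C={"IE": 60.0, "EI": 60.0, "EE": 100.0, "II": 100.0},
    )


@pytest.fixture
def small_plastic_config(table_params):
    return SimulationConfig(
        params=table_params,
        plasticity={"IE": make_rule("hebbian")},
        initial_weight={"IE": 200.0},
        burn_in=500.0,
        seed=7,
    )
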