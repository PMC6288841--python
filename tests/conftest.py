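import numpy as np
import pytest

from gxepred.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-line, 3-environment trial with moderate G*E, shared across tests."""
    cfg = SimConfig(
        n_lines=30,
        n_envs=3,
        n_markers=200,
        env_means=[10.0, 12.0, 8.0],
        var_g=1.0,
        var_ge=0.5,
        var_e=1.0,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
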