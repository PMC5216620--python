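import numpy as np
import pytest

from connage.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_older=10, n_younger=10, n_timepoints=250, rng_seed=7,
        insula_decline_slope=-0.012, parietal_increase_delta=0.1,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)
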