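import numpy as np
import pytest

import spectransfer as st


@pytest.fixture(scope="session")
def small_config() -> st.GeneratorConfig:
    """Scaled-down generator: same structure, fewer plants, for fast tests."""
    return st.GeneratorConfig(n_plants_per_group=8, leaves_per_plant=2, seed=0)


@pytest.fixture(scope="session")
def small_data(small_config) -> dict:
    """Index tables for the three default experiments of the small generator."""
    return {
        exp: st.index_table(st.simulate_experiment(small_config, exp))
        for exp in small_config.domains
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
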