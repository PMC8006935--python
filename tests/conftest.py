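import numpy as np
import pytest

from gliomasyn.defaults import (
    default_drug_params,
    default_growth_params,
    default_initial_state,
)


@pytest.fixture(scope="session")
def growth_params():
    return default_growth_params()


@pytest.fixture(scope="session")
def initial_state():
    return default_initial_state()


@pytest.fixture(scope="session")
def drug_params_ac26():
    return default_drug_params("AC26")


@pytest.fixture(scope="session")
def synthetic_dataset(growth_params):
    """One shared noisy 96-h growth dataset (fixed seed)."""
    from gliomasyn.synthetic_data import generate_growth_data
    return generate_growth_data(growth_params, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
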