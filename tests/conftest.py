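import numpy as np
import pytest

from abekin import packaged_fixture, simulate_batch


@pytest.fixture(scope="session")
def fit_a():
    return packaged_fixture("fit_A")


@pytest.fixture(scope="session")
def shinto_initial():
    return packaged_fixture("shinto_initial")


@pytest.fixture(scope="session")
def base_trajectory(fit_a, shinto_initial):
    """Reference 60 h batch at default tolerances, shared across tests."""
    return simulate_batch(shinto_initial, fit_a)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231124)
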