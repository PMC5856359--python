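import numpy as np
import pytest

from banditrials import compute_gittins_table, load_table


@pytest.fixture
def rng():
    return np.random.default_rng(20170628)


@pytest.fixture(scope="session")
def table995():
    return load_table(0.995)


@pytest.fixture(scope="session")
def table99():
    return load_table(0.99)


@pytest.fixture(scope="session")
def table90():
    return load_table(0.9)


@pytest.fixture(scope="session")
def small_table():
    """Quickly computed table at a mild discount, for rule-level tests."""
    return compute_gittins_table(0.8, 12, grid_points=201)
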