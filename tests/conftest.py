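import numpy as np
import pytest

from cetfinder import (make_background, synthetic_cdr_table,
                       synthetic_nt_table)


@pytest.fixture(scope="session")
def cdr_table():
    return synthetic_cdr_table()


@pytest.fixture(scope="session")
def nt_table():
    return synthetic_nt_table()


@pytest.fixture(scope="session")
def small_background():
    """80-clonotype β background with element pools (session-cached)."""
    return make_background(80, chain="beta", seed=5)


@pytest.fixture(scope="session")
def alpha_background():
    return make_background(60, chain="alpha", seed=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
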