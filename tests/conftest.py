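import numpy as np
import pytest

import stericlv as slv


@pytest.fixture(scope="session")
def small_lattice_env():
    """Ordered lattice small enough for exhaustive checks."""
    return slv.make_environment(L=42.0, dx=10.5, R=3.0, delta=0.0, seed=1)


@pytest.fixture(scope="session")
def standard_lattice_env():
    """Paper-scale ordered lattice (L=150, dx/R=3.5, R=3)."""
    return slv.make_environment(L=150.0, dx=10.5, R=3.0, delta=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
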