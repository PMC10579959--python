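import numpy as np
import pytest

from atrialign.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One labeled left-atrium phantom shared across tests (read-only)."""
    return generate_phantom(PhantomParams(seed=0))


@pytest.fixture(scope="session")
def small_phantom():
    """A coarser phantom for tests that loop over many registrations."""
    return generate_phantom(PhantomParams(seed=1, target_spacing=2.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
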