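import numpy as np
import pytest

from mpfkit.config import default_protocols
from mpfkit.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture(scope="session")
def mt_protocol(protocols):
    return protocols["mt_w"]


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-grid phantom for fast unit tests (full defaults are exercised
    in the acceptance suite)."""
    return make_phantom(PhantomSpec(shape=(48, 48, 12)))


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
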