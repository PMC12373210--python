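import numpy as np
import pytest

from tomofield.geometry import SourceSetup
from tomofield.phantom import default_setup, make_dataset, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_setup():
    """16x16 detector matched to a 300 mm object."""
    return default_setup(16, 300.0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """One 16^3 phantom with 8 circular views (session-cached; treat as read-only)."""
    return make_dataset(np.random.default_rng(7), n_patients=1, dims=16,
                        n_views=8, extent_mm=300.0)


@pytest.fixture(scope="session")
def phantom_32():
    return make_phantom(np.random.default_rng(42), dims=32, extent_mm=300.0)
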