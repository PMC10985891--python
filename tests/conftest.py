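import numpy as np
import pytest

import vessel3 as v
from vessel3.nn import set_default_dtype
from vessel3.presets import small_phantom_spec


@pytest.fixture(autouse=True)
def _float32_default():
    """Keep the global parameter dtype at float32 unless a test opts out."""
    set_default_dtype(np.float32)
    yield
    set_default_dtype(np.float32)


@pytest.fixture
def float64_params():
    set_default_dtype(np.float64)
    yield
    set_default_dtype(np.float32)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def phantom_batch(small_spec):
    """30 desk-scale phantoms shared by property tests."""
    return v.make_dataset(small_spec, 30, seed=42)


@pytest.fixture(scope="session")
def default_batch():
    """Full-resolution (256x256) phantoms from the default spec."""
    return v.make_dataset(v.PhantomSpec(), 200, seed=7)
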