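import numpy as np
import pytest

from weakbeat import autodiff


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 (finite-difference friendly)."""
    old = autodiff.DTYPE
    autodiff.set_dtype(np.float64)
    yield
    autodiff.set_dtype(old)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
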