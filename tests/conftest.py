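import numpy as np
import pytest

from endofuse.synthetic import PhantomParams, default_battery, generate_phantom


@pytest.fixture(scope="session")
def battery42():
    """The canonical six-phantom fixture battery."""
    return default_battery(42)


@pytest.fixture(scope="session")
def dark_phantom():
    """A small dark phantom for fast per-module checks."""
    return generate_phantom(
        PhantomParams(height=64, width=64, darkening_gamma=2.5, n_vessels=4, seed=42)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
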