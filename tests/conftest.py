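import numpy as np
import pytest

from parpolar import SolverOptions, default_params


@pytest.fixture(scope="session")
def params():
    """Anchor-point parameters (alpha/l = 1.2, beta_scaled = 100)."""
    return default_params().with_nondim(1.2, 100.0)


@pytest.fixture(scope="session")
def base_params():
    return default_params()


@pytest.fixture()
def fast_options():
    """Small grid / short horizon for unit-level dynamics tests."""
    return SolverOptions(n=64, t_max=600.0, record=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
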