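import numpy as np
import pytest

from holimap.model import build_autoreg, compile_reactions


@pytest.fixture(scope="session")
def autoreg_bursty():
    """Bursty positive-feedback autoregulation (B = 1, h = 1)."""
    return build_autoreg(sigma_b=0.1, sigma_u=1.0, rho_b=50.0, rho_u=5.0,
                         d=1.0, h=1, p=0.5)


@pytest.fixture(scope="session")
def autoreg_system(autoreg_bursty):
    return compile_reactions(autoreg_bursty)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
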