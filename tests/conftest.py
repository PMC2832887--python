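import numpy as np
import pytest

import promodyn as pmd


@pytest.fixture
def telegraph():
    """Two-state promoter with kon = 0.2*5 = 1/s, koff = 3/s, rho = (0, 8)."""
    return pmd.two_state(kon0=0.2, conc=5.0, koff=3.0, rho_off=0.0, rho_on=8.0)


@pytest.fixture
def telegraph_gm(telegraph):
    return pmd.build_generator(telegraph)


@pytest.fixture
def constant_promoter():
    """Single effective state (negligible switching), rho = 2/s everywhere."""
    return pmd.PromoterSystem(
        tf_names=("A",),
        k0=np.array([[1e-12, 1e-12]]),
        concentrations=np.array([1.0]),
        rho=np.array([2.0, 2.0]),
    )


@pytest.fixture
def cascade():
    return pmd.CascadeParams(gamma=0.1, beta=1.0, gamma_p=0.05)
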