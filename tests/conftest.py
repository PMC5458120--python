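"""Shared fixtures: small, fast parameter sets for unit tests."""
import numpy as np
import pytest

from motorclutch import SimulationParameters


@pytest.fixture
def small_params() -> SimulationParameters:
    """A miniature cell: fast to simulate, same physics as the full sets."""
    return SimulationParameters(
        k_on=1.0, k_off_star=0.1, F_b=2.0, kappa_c=0.8, kappa_s=1.0,
        kappa_cell=1e4, F_m=2.0, v_m_star=120.0, v_p_star=200.0,
        k_mod_star=1.0, k_cap=0.001, l_in=5000.0, l_min=500.0,
        n_m_tot=40, n_c_tot=30, n_m_star=10, n_c_star=8, n_c_cell=4,
        A_T=100000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
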