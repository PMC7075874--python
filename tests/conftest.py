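import numpy as np
import pytest

from nlari import ModelParams, simulate_nlari

# the stable-regime reference parameter set used throughout: printed
# resistance/noise values with a mid-range restoration coefficient
ALPHA = 0.7786
SIGMA = 0.0275


@pytest.fixture(scope="session")
def stable_params():
    return ModelParams(omega=1e-4, sigma=SIGMA, alpha=ALPHA, beta=0.3)


@pytest.fixture(scope="session")
def near_boundary_params():
    # gamma ~ 0.017, the edge-of-stability case
    return ModelParams(omega=1e-4, sigma=SIGMA, alpha=ALPHA, beta=0.017 * (4 - 2 * ALPHA))


@pytest.fixture(scope="session")
def unit_root_params():
    return ModelParams(omega=0.0, sigma=SIGMA, alpha=ALPHA, beta=0.0)


@pytest.fixture(scope="session")
def stable_sim(stable_params):
    """One 900-point stable-regime trajectory (the study's window length)."""
    return simulate_nlari(stable_params, 900, x0=4.1, seed=12345)


@pytest.fixture(scope="session")
def stable_hr(stable_sim):
    return np.exp(stable_sim.x)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
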