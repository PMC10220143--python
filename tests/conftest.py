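import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from wfrecomb import ModelParams, SimConfig, euler_maruyama

X0_DEFAULT = np.array([0.4, 0.2, 0.2, 0.2])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def x0():
    return X0_DEFAULT.copy()


def random_simplex(rng, d, n=1, interior=True):
    pts = rng.dirichlet(np.ones(d), size=n)
    if interior:
        pts = np.clip(pts, 1e-9, None)
        pts /= pts.sum(axis=1, keepdims=True)
    return pts[0] if n == 1 else pts


@pytest.fixture
def interior_points(rng):
    return random_simplex(rng, 4, n=100)


@pytest.fixture
def neutral_params():
    return ModelParams(allele_counts=(2, 2), theta_A=5.0, theta_B=5.0, rho=5.0)


@pytest.fixture
def short_trajectory(neutral_params):
    """A short interior stochastic path with stored Brownian increments."""
    cfg = SimConfig(dt=5e-4, T=0.5, seed=6, store_brownian=True)
    return euler_maruyama(neutral_params, X0_DEFAULT, cfg)
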