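import numpy as np
import pytest

from discoset import MixtureParams


def random_params(rng: np.random.Generator, K: int) -> MixtureParams:
    """A valid random parameter draw with well-formed simplexes and signs."""
    pi = rng.dirichlet(np.ones(3))
    rho = rng.dirichlet(np.ones(3), size=K).T
    mu = np.vstack([
        np.zeros(K),
        rng.uniform(0.5, 4.0, size=K),
        -rng.uniform(0.5, 4.0, size=K),
    ])
    sigma2 = np.vstack([
        np.ones(K),
        rng.uniform(0.3, 3.0, size=(2, K)),
    ])
    return MixtureParams(lam=float(rng.uniform(0, 1)), pi=pi, rho=rho,
                         mu=mu, sigma2=sigma2)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def params_k3(rng):
    return random_params(rng, 3)
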