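import numpy as np
import pytest

from cernacap import KineticParameters, Occupancies
from cernacap.presets import preset


@pytest.fixture(scope="session")
def fig2():
    return preset("fig2")


@pytest.fixture(scope="session")
def birth_death():
    """Fully decoupled network: each free species is a Poisson birth-death
    process (k+ = 0 removes every complex reaction)."""
    params = KineticParameters(
        b1=50.0, b2=100.0, beta=30.0, d1=0.1, d2=0.1, delta=0.1,
        kplus1=0.0, kplus2=0.0, kminus1=0.0, kminus2=0.0,
        kappa1=0.0, kappa2=0.0, sigma1=0.0, sigma2=0.0,
    )
    occ = Occupancies(n1=0.5, n2=0.99, nmu=0.9)
    return params, occ


def random_stable_system(rng: np.random.Generator, n: int = 5):
    """Random strictly stable relaxation matrix and PSD diffusion matrix."""
    M = rng.normal(size=(n, n))
    shift = max(np.linalg.eigvals(M).real.max(), 0.0) + rng.uniform(0.5, 2.0)
    A = M - shift * np.eye(n)
    S = rng.normal(size=(n, n))
    Gamma = S @ S.T
    return A, Gamma
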