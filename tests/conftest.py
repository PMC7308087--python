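import numpy as np
import pytest

from rtopmap.scheme import make_acquisition_scheme
from rtopmap.synthetic import GaussianCompartment


@pytest.fixture(scope="session")
def hcp_scheme():
    """Default 3-shell scheme (b = 1000/2000/3000, 90 dirs, 6 b0)."""
    return make_acquisition_scheme(seed=0)


@pytest.fixture(scope="session")
def free_water():
    return [GaussianCompartment.isotropic(1.0, 3.0e-3)]


def sample_vmf(rng, mu, kappa, n):
    """von Mises-Fisher sample on S^2 (inverse-CDF for the polar angle)."""
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0, 2 * np.pi, size=n)
    # orthonormal frame around mu
    a = np.array([1.0, 0.0, 0.0])
    if abs(mu @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    return (w[:, None] * mu
            + (s * np.cos(phi))[:, None] * e1
            + (s * np.sin(phi))[:, None] * e2)
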