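import numpy as np
import pytest

from pnpiv.flux import BoundaryState, SpeciesPair
from pnpiv.geometry import cylindrical_channel


@pytest.fixture(scope="session")
def geom():
    """Reference channel: neck on (0.4, 0.48), r0 = 0.5, Q0 = 0.008."""
    return cylindrical_channel(0.4, 0.48, 0.5, Q0=0.008)


@pytest.fixture(scope="session")
def species():
    """1:1 electrolyte with the reference diffusion coefficients."""
    return SpeciesPair(1, -1, 2.032, 1.334)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230119)


def random_parameter_set(rng):
    """Admissible random (species, boundary, geometry) draw for dual-path tests."""
    z1 = int(rng.integers(1, 4))
    z2 = -int(rng.integers(1, 3))
    D1, D2 = rng.uniform(0.3, 3.0, size=2)
    L1 = rng.uniform(2.0, 20.0)
    R1 = L1 * rng.uniform(0.3, 0.9)  # keep L1 != R1
    sigma, rho = rng.uniform(0.5, 2.0, size=2)
    a = rng.uniform(0.1, 0.6)
    b = rng.uniform(a + 0.05, 0.9)
    r0 = rng.uniform(0.2, 1.0)
    sp = SpeciesPair(z1, z2, D1, D2)
    bs = BoundaryState(V=rng.uniform(-2.0, 2.0), L1=L1, R1=R1,
                       sigma=sigma, rho=rho)
    g = cylindrical_channel(a, b, r0, Q0=rng.uniform(-0.02, 0.02))
    return sp, bs, g
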