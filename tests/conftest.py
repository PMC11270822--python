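import numpy as np
import pytest

import qmcforces as q


@pytest.fixture(scope="session")
def hydrogen():
    return q.make_hydrogenic_atom(1.0)


@pytest.fixture(scope="session")
def hydrogen_exact(hydrogen):
    return q.exact_wavefunction(hydrogen)


@pytest.fixture(scope="session")
def harmonic():
    return q.make_harmonic_atom(1.0)


@pytest.fixture(scope="session")
def harmonic_exact(harmonic):
    return q.exact_wavefunction(harmonic)


@pytest.fixture(scope="session")
def two_center():
    return q.make_two_center_system(2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def triangle_reference():
    """Planar 3-atom reference with well-separated pair distances
    (2.0, 2.7, 3.5 bohr), so the sorted descriptor keeps a stable order."""
    x = (2.0**2 + 2.7**2 - 3.5**2) / 4.0
    y = np.sqrt(2.7**2 - x**2)
    return q.Geometry(
        np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [x, y, 0.0]]),
        np.ones(3),
        ("X", "X", "X"),
    )
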