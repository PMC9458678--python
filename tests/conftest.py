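import numpy as np
import pytest

from saxsens.structures import Conformer


def make_conformer(coords, masses=None, resids=None, names=None, elements=None,
                   chains=None, resnames=None, id="0"):
    """Bare-bones conformer from a coordinate array for unit tests."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return Conformer(
        elements=elements if elements is not None else ["C"] * n,
        names=names if names is not None else ["CA"] * n,
        resids=resids if resids is not None else np.arange(1, n + 1),
        resnames=resnames if resnames is not None else ["ALA"] * n,
        chains=chains if chains is not None else ["A"] * n,
        masses=masses if masses is not None else np.ones(n),
        coords=coords,
        id=id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_conformer(rng):
    """50 unit-mass beads in a ~20 Å blob."""
    return make_conformer(rng.normal(scale=8.0, size=(50, 3)))


def random_rotation(rng):
    """Haar-random rotation matrix via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
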