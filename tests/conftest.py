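import numpy as np
import pytest

from myofe import MaterialParams


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    """Default (calibrated) material parameter set."""
    return MaterialParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230518)


def random_deformation(rng, scale=0.15):
    """Random deformation gradient with det > 0, moderate strain."""
    while True:
        F = np.eye(3) + rng.uniform(-scale, scale, (3, 3))
        if np.linalg.det(F) > 0.3:
            return F


def random_rotation(rng):
    """Haar-ish random rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
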