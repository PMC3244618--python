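import numpy as np
import pytest

from cathsim import TubeSpec, make_tube


@pytest.fixture(scope="session")
def straight_tube():
    """Wide straight tube along +x: radius 5 mm, length 60 mm."""
    return make_tube(TubeSpec(radius=5.0, kind="straight", length=60.0,
                              circumferential_resolution=16, axial_resolution=24))


@pytest.fixture(scope="session")
def curved_tube_spec():
    """Curved phantom: 3 mm lumen, 90-degree bend of 12 mm radius."""
    return TubeSpec(radius=3.0, kind="curved", bend_radius=12.0, bend_angle=np.pi / 2,
                    entry_length=10.0, exit_length=10.0,
                    circumferential_resolution=20, axial_resolution=48)


@pytest.fixture(scope="session")
def curved_tube(curved_tube_spec):
    return make_tube(curved_tube_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform-ish random rotation matrix from a QR decomposition."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
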