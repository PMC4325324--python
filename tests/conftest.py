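import numpy as np
import pytest

from pathmetad.geometry import Configuration


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()


@pytest.fixture
def hinge_pair():
    """Two 6-particle configurations: a static 'core' triangle-pair and a
    3-particle block rotated 90 deg about the z-axis through the origin."""
    core = np.array([[0.0, 0.0, 0.0], [-0.5, 0.0, 0.0], [-0.25, 0.4, 0.1]])
    block = np.array([[1.0, 0.0, 0.0], [1.3, 0.2, 0.0], [1.3, -0.2, 0.0]])
    a = np.vstack([core, block])
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    b = np.vstack([core, block @ rot.T])
    sels = {"core": np.arange(3), "block": np.arange(3, 6)}
    return Configuration(a, selections=sels), Configuration(b, selections=sels)
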