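import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ifpkit.synth import make_toy_complex


@pytest.fixture(scope="session")
def toy_template():
    return make_toy_complex()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_rigid(rng):
    """One uniform random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


def random_hexagon(rng, radius=1.39):
    """Planar hexagon with random center and orientation."""
    ang = np.arange(6) * np.pi / 3.0
    flat = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)
    R, t = random_rigid(rng)
    return flat @ R.T + t
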