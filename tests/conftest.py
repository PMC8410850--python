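import numpy as np
import pytest

from fivetm import synthetic
from fivetm.structure import default_segment_map


@pytest.fixture(scope="session")
def seg():
    return default_segment_map()


@pytest.fixture(scope="session")
def toy():
    """Noise-free toy receptor with all planted geometry at its defaults."""
    structure, truth = synthetic.make_toy_receptor()
    return structure, truth


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0].first


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans
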