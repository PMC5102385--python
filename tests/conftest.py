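import numpy as np
import pytest

from gagfold import synthetic_data as sd


@pytest.fixture(scope="session")
def n_bundle():
    """A 4-helix bundle used across alignment tests."""
    return sd.build_bundle(sd.BundleSpec(sd.N_LAYOUT, seed=1))


@pytest.fixture(scope="session")
def c_bundle():
    """A 5-helix bundle."""
    return sd.build_bundle(sd.BundleSpec(sd.C_LAYOUT, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_rigid_transform(rng):
    """A random proper rotation + translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)],
        ]
    )
    return rot, rng.uniform(-20, 20, 3)
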