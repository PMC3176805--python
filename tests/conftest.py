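import numpy as np
import pytest

from restkit import FixtureSpec, Mask, Volume3D, Volume4D, make_rs_volume
from restkit.synthetic_fixtures import default_affine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_vol(rng):
    """A 6x6x6x40 noise volume, TR = 2 s, 3 mm voxels."""
    data = 100 + rng.standard_normal((6, 6, 6, 40))
    return Volume4D(data=data, affine=default_affine(3.0), tr=2.0)


@pytest.fixture
def full_mask(small_vol):
    return Mask.full(small_vol)


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted-signal fixture (shared across tests)."""
    spec = FixtureSpec.default(seed=11)
    return make_rs_volume(spec)
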