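import numpy as np
import pytest

from ritfm import ElasticSubstrate, PhantomSpec, make_bead_phantom

PITCH = 0.183


@pytest.fixture(scope="session")
def soft_substrate():
    return ElasticSubstrate(E=1200.0, nu=0.5)


@pytest.fixture(scope="session")
def stiff_substrate():
    return ElasticSubstrate(E=11000.0, nu=0.5)


@pytest.fixture(scope="session")
def bead_volume_small():
    """48^3 bead phantom at instrument pitch/density (session-cached)."""
    return make_bead_phantom(PhantomSpec(volume_shape=(48, 48, 48), seed=7))


@pytest.fixture(scope="session")
def bead_volume_flat():
    """Shallow wide phantom for traction round trips."""
    return make_bead_phantom(PhantomSpec(volume_shape=(32, 96, 96), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
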