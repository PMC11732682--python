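import numpy as np
import pytest

from morphcascade.phantom import DeformationSpec, PhantomSpec, make_pair, make_phantom, make_smooth_field
from morphcascade.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.random((10, 10, 10)))


@pytest.fixture(scope="session")
def phantom32():
    """One 32^3 phantom with labels (session-cached: generation is cheap but
    several modules reuse it)."""
    return make_phantom(PhantomSpec(size=32, seed=7))


@pytest.fixture(scope="session")
def pair32():
    """Fixed/moving pair with known truth field."""
    return make_pair(PhantomSpec(size=32, seed=7),
                     DeformationSpec(size=32, max_disp=3.0,
                                     smoothness_sigma=4.0, seed=7))


@pytest.fixture
def smooth_field16():
    return make_smooth_field(DeformationSpec(size=16, max_disp=1.5,
                                             smoothness_sigma=3.0, seed=5))
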