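import numpy as np
import pytest

from nvcvis import phantom
from nvcvis.volumes_io import Volume


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(
        shape=(64, 64, 64),
        seed=7,
        tof_rot_deg=(2.0, -1.5, 1.0),
        tof_shift_mm=(0.8, -0.6, 0.5),
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """One 64^3 phantom pair shared across read-only tests."""
    return phantom.generate(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    data = rng.normal(100.0, 10.0, (12, 12, 12))
    return Volume.from_spacing(data, 0.4)
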