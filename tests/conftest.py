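import numpy as np
import pytest

from lymphomorph import generate_phantom
from lymphomorph.phantom import PhantomSpec
from lymphomorph.presets import mandibular_spec, registration_spec


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Small but fully featured phantom spec for fast unit tests."""
    return PhantomSpec(
        shape_voxels=(96, 104, 112),
        voxel_um=7.2,
        ln_radii_um=(310.0, 340.0, 370.0),
        follicle_count=4,
        follicle_diam_um=(140.0, 20.0),
        nodule_count=5,
        nodule_diam_true_um=(100.0, 20.0),
        nodule_diam_window_um=(40.0, 150.0),
        capillary_fraction={"dcu": 0.10, "follicle": 0.22},
        adipocyte_count=3,
        adipocyte_diam_um=(30.0, 60.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def young_pair():
    """The committed young-mouse fixture pair (28 and 29 nodules)."""
    return [generate_phantom(mandibular_spec("young", rep))[1]
            for rep in range(2)]


@pytest.fixture(scope="session")
def old_pair():
    """The committed old-mouse fixture pair (59 and 60 nodules)."""
    return [generate_phantom(mandibular_spec("old", rep))[1]
            for rep in range(2)]


@pytest.fixture(scope="session")
def registration_volume():
    vol, _ = generate_phantom(registration_spec())
    return vol


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
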