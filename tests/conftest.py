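import numpy as np
import pytest

from valvequant import ClassColorReference, PhantomSpec, generate_ct_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A compact phantom (~10k ROI voxels) shared by read-only tests."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        target_volumes={"fibrotic": 0.6, "calcific": 0.2125},
        blood_fraction=0.35,
        seed=7,
    )
    return spec, generate_ct_phantom(spec)


@pytest.fixture(scope="session")
def color_ref():
    return ClassColorReference.movat_default()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
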