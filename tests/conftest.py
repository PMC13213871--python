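import numpy as np
import pytest

from hemoforce.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def oscillation_phantom():
    """Default-scale uniform-oscillation phantom (32^3, 25 frames)."""
    return make_phantom(PhantomSpec(kind="uniform_oscillation"))


@pytest.fixture(scope="session")
def poiseuille_phantom():
    return make_phantom(PhantomSpec(kind="poiseuille"))


@pytest.fixture(scope="session")
def rotation_phantom():
    return make_phantom(PhantomSpec(kind="solid_rotation"))


@pytest.fixture(scope="session")
def blob_phantom():
    return make_phantom(PhantomSpec(kind="contracting_blob"))


@pytest.fixture()
def small_spec():
    """Small grid for tests that loop or write files."""
    return PhantomSpec(kind="uniform_oscillation", grid=(12, 12, 12), n_frames=10,
                       mask_volume_ml=1.0)
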