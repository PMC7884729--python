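import numpy as np
import pytest

from segpick import SceneSpec, make_micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A clean 128x128 scene with 8 disk particles and exact ground truth."""
    spec = SceneSpec(
        image_size=(128, 128), n_particles=8, particle_radius_px=6,
        particle_contrast=0.5, seed=42,
    )
    return make_micrograph(spec)


@pytest.fixture
def contaminated_scene():
    """A 256x256 scene with ice blobs, carbon edge and illumination gradient."""
    spec = SceneSpec(
        image_size=(256, 256), n_particles=10, particle_radius_px=10,
        particle_contrast=0.5, ice_blobs=2, carbon_edge=True,
        illumination_gradient=0.2, seed=7,
    )
    return make_micrograph(spec)
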