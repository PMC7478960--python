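import numpy as np
import pytest

from mck.simulate import SceneSpec


@pytest.fixture
def small_spec():
    """Tiny noiseless scene for geometry-level tests."""
    return SceneSpec(field_size=(64, 64), pixel_size=32.0, frame_interval=1.0,
                     n_frames=1, psf_sigma=42.0, seed=7)


@pytest.fixture
def sharp_spec():
    """Noiseless scene without PSF blur (exact rasterization checks)."""
    return SceneSpec(field_size=(64, 64), pixel_size=32.0, frame_interval=1.0,
                     n_frames=1, psf_sigma=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
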