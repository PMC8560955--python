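import numpy as np
import pytest

from lesionsr.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small textured-lesion phantom shared across read-only tests."""
    spec = PhantomSpec(
        shape=(12, 20, 20),
        lesion_center=(6, 10, 10),
        lesion_radius_vox=4.0,
        texture_corr_vox=1.5,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_roi(rng, shape=(4, 4, 4), n_levels=3):
    """Random small quantized-ROI input: volume + non-trivial mask."""
    vol = rng.integers(0, n_levels, size=shape).astype(float)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return vol, mask
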