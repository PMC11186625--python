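import numpy as np
import pytest

from photorecon import (PhantomSpec, ReferenceVolume, SliceStack,
                        make_phantom)


@pytest.fixture(scope="session")
def phantom():
    """Default hemisphere phantom (session-scoped: deterministic)."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def surface_ref(phantom):
    return ReferenceVolume(volume=phantom.mask, voxel_size=phantom.voxel_size,
                           kind="surface_mask")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_textured_stack(n=6, h=24, w=24, pixel_size=1.0, thickness=1.0,
                        seed=1, identical=True):
    """Stack of textured slices with a rectangular binary mask."""
    r = np.random.default_rng(seed)
    mask = np.zeros((h, w))
    mask[h // 4:3 * h // 4, w // 5:4 * w // 5] = 1.0
    if identical:
        base = r.uniform(0.2, 0.8, (h, w)) * mask
        images = np.stack([base] * n)
    else:
        images = np.stack([r.uniform(0.2, 0.8, (h, w)) * mask
                           for _ in range(n)])
    masks = np.stack([mask] * n)
    return SliceStack(images=images, masks=masks, pixel_size=pixel_size,
                      nominal_thickness=thickness)
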