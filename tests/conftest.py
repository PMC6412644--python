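import numpy as np
import pytest

from dropvision.segment import CarrierImage
from dropvision.synth import SceneSpec, generate_scene


def make_disk_image(
    centers, radii, shape=(64, 64), bg=0.9, fg=0.1, scale=0.005
) -> CarrierImage:
    """Hard-edged dark disks on a bright background (no noise)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    px = np.full(shape, bg, dtype=float)
    for (cy, cx), r in zip(centers, radii):
        px[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = fg
    return CarrierImage(pixels=px, scale_cm_per_px=scale, polarity="dark")


@pytest.fixture(scope="session")
def small_scene():
    """50 disjoint droplets on a 256 px window."""
    return generate_scene(
        SceneSpec(width_px=256, height_px=256, n_droplets=50,
                  adhesion_fraction=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def adhesive_scene():
    """200 droplets, 15% fused into adhesive pairs (study conditions)."""
    return generate_scene(SceneSpec(seed=5))
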