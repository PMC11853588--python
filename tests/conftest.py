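import math

import numpy as np
import pytest

from loricavol import ZStack


def digitized_sphere_stack(radius_um: float, voxel: float = 0.5) -> ZStack:
    """Binary stack of a sphere rasterized by voxel-centre membership."""
    n = int(math.ceil(2 * radius_um / voxel)) + 4
    centre = n * voxel / 2.0
    coords = (np.arange(n) + 0.5) * voxel
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    mask = (zz - centre) ** 2 + (yy - centre) ** 2 + (xx - centre) ** 2 \
        <= radius_um**2
    return ZStack(mask, voxel_xy=voxel, voxel_z=voxel)


def rasterized_half_disc(radius_px: int) -> np.ndarray:
    """Half-disc mask (rows axial, rotation axis on column border 0)."""
    n = 2 * radius_px
    rows = (np.arange(n) + 0.5) - radius_px
    cols = np.arange(radius_px + 1) + 0.5
    return rows[:, None] ** 2 + cols[None, :] ** 2 <= radius_px**2


@pytest.fixture(scope="session")
def sphere_stack_r10() -> ZStack:
    return digitized_sphere_stack(10.0, voxel=0.5)
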