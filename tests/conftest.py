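"""Shared fixtures: tiny grids, hand-placed streamlines, synthetic locmaps."""

import numpy as np
import pytest

from dsdkit.composite import RasterConfig
from dsdkit.synthetic import mini_template
from dsdkit.types import StreamlineBundle, Volume3D


@pytest.fixture
def template():
    """Default 40x48x40 voxel 2 mm template."""
    return mini_template()


@pytest.fixture
def tiny_grid():
    """10^3 grid, 2 mm voxels, origin at the corner voxel centre."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return Volume3D(np.zeros((10, 10, 10)), affine, space_tag="tiny")


def straight_streamline(axis: int, fixed: tuple, lo: float, hi: float, n: int = 40):
    """Axis-aligned streamline in world mm on the tiny grid."""
    pts = np.zeros((n, 3))
    other = [i for i in range(3) if i != axis]
    pts[:, axis] = np.linspace(lo, hi, n)
    pts[:, other[0]] = fixed[0]
    pts[:, other[1]] = fixed[1]
    return pts


@pytest.fixture
def hand_bundles(tiny_grid):
    """Three normative subjects with hand-placed streamlines on the tiny grid.

    Subject 0: one streamline along x at (y,z)=(4,4) mm.
    Subject 1: same x-line plus one along y at (x,z)=(10,10).
    Subject 2: one diagonal streamline.
    """
    sx = straight_streamline(0, (4.0, 4.0), 0.0, 18.0)
    sy = straight_streamline(1, (10.0, 10.0), 0.0, 18.0)
    diag = np.linspace([0.0, 0.0, 0.0], [18.0, 18.0, 18.0], 60)
    return [
        StreamlineBundle("s0", [sx]),
        StreamlineBundle("s1", [sx.copy(), sy]),
        StreamlineBundle("s2", [diag]),
    ]


def make_locmaps(coords, patient_ids=None, mapping_mode="autoscale",
                 grid_size=260):
    """Rasterize synthetic morphospace coordinates into localization maps.

    Smaller grids keep the standard 13 mm window (pixel size scales up), so
    the 1 mm kernel stays well inside the grid."""
    cfg = RasterConfig(grid_size=grid_size, pixel_size=0.05 * 260 / grid_size,
                       mapping_mode=mapping_mode)
    rg = cfg.fit(np.asarray(coords, dtype=float))
    return rg.rasterize_cohort(np.asarray(coords, dtype=float), patient_ids), rg


@pytest.fixture
def cluster_coords():
    """60 coordinates in three well-separated clusters + cluster labels."""
    rng = np.random.default_rng(7)
    centers = np.array([[2.0, 2.0], [9.0, 3.0], [5.0, 9.0]])
    labels = np.repeat(np.arange(3), 20)
    coords = centers[labels] + 0.3 * rng.standard_normal((60, 2))
    return coords, labels
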