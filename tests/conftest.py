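"""Shared fixtures: calibrated scaffold designs reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

import tpmscaffold as tp

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

CELL = tp.UnitCell(2.5)
# L/64 pitch: fine enough for mesh-volume agreement, still <= 40 um
FINE_PITCH_UM = 2.5 / 64 * 1000.0  # 39.0625


@pytest.fixture(scope="session")
def cylinder_domain():
    """The compression-specimen preset: Ø8 mm x 3 mm cylinder."""
    return tp.DomainSpec("cylinder", (8.0, 3.0), FINE_PITCH_UM)


@pytest.fixture(scope="session")
def period_box():
    """One full TPMS period sampled at 64 voxels per edge."""
    return tp.DomainSpec("box", (CELL.edge_length,) * 3, FINE_PITCH_UM)


@pytest.fixture(scope="session")
def calibrated_scaffolds(cylinder_domain):
    """All three geometries calibrated to 20 % porosity on the cylinder.

    Returns ``{geometry: (model, calibration, scalar_grid)}``.
    """
    return {
        g: tp.build_scaffold(g, CELL, cylinder_domain, target_void_fraction=0.2)
        for g in tp.GEOMETRIES
    }


@pytest.fixture()
def unit_cube_mesh():
    """A 12-triangle unit cube with outward orientation.

    Canonicalized so vertices are ordered by first appearance in the face
    list; a binary STL write->read round trip then reproduces the arrays
    exactly.
    """
    from tpmscaffold.mesh import _weld
    verts = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z=0), outward -z
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # y=0
            [2, 3, 7], [2, 7, 6],  # y=1
            [1, 2, 6], [1, 6, 5],  # x=1
            [3, 0, 4], [3, 4, 7],  # x=0
        ]
    )
    return _weld(verts[faces])
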