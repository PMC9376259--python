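"""Shared fixtures: tiny meshes and a small label space for pipeline tests.

Everything is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import sfmvpa as m
from sfmvpa.mesh import SurfaceMesh


@pytest.fixture(scope="session")
def chain_mesh() -> SurfaceMesh:
    """10 collinear vertices at 0..9 mm (faces empty; pure point geometry)."""
    verts = np.zeros((10, 3))
    verts[:, 0] = np.arange(10)
    return SurfaceMesh(verts, np.empty((0, 3), int))


@pytest.fixture(scope="session")
def chain_parcellation(chain_mesh):
    """The hand-traceable 5-label parcellation of the chain (r=0.95, R=1.9)."""
    return m.double_radius_divide(chain_mesh, r=0.95, R=1.9)


@pytest.fixture(scope="session")
def label_space():
    """102-label parcellation of a 2562-vertex icosphere (radius 50 mm).

    Vertex spacing ~3.6 mm, dividing radius 7.5 mm, searchlight radius
    20 mm (~3-5 member labels), adjacency threshold 4 mm.
    """
    from sfmvpa.validation import make_validation_space

    return make_validation_space()
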