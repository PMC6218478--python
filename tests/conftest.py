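import numpy as np
import pytest

from epifold.builder import assign_stripe, build_hex_tissue
from epifold.geometry import Cell, TissueMesh
from epifold.mechanics import MechanicalParams


@pytest.fixture
def unit_cube():
    """A single cubic cell with unit faces in a large box (no wrapping)."""
    ap = np.array([[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
    ba = ap.copy()
    ba[:, 2] = 0.0
    pos = np.vstack([ap, ba])
    return TissueMesh(pos, [Cell(0, [0, 1, 2, 3], [4, 5, 6, 7])], (10.0, 10.0))


@pytest.fixture(scope="session")
def small_tissue():
    """Relaxed 6x6 periodic packing with a 2-row pre-fold stripe."""
    mesh, params = build_hex_tissue(6, 6)
    assign_stripe(mesh, 2)
    return mesh, params


@pytest.fixture(scope="session")
def baseline_10():
    """Relaxed 10x10 periodic packing, 4x basal:apical tensions, no stripe."""
    return build_hex_tissue(10, 10)


def hexagonal_prism_mesh(side=1.0, height=2.0, z0=0.0):
    """A single regular hexagonal-prism cell in a large box."""
    ang = np.pi / 2 + np.arange(6) * np.pi / 3
    ap = np.column_stack([side * np.cos(ang), side * np.sin(ang), np.full(6, z0 + height)])
    ba = ap.copy()
    ba[:, 2] = z0
    pos = np.vstack([ap, ba])
    return TissueMesh(pos + np.array([5.0, 5.0, 0.0]), [Cell(0, np.arange(6), np.arange(6, 12))], (20.0, 20.0))
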