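"""Shared fixtures: synthetic pocket, probe ligands, and prebuilt grids.

Grid builds and GA searches dominate the suite's runtime, so the pocket
grid set is session-scoped and the docking cube is kept small (10 Å edge,
0.5 Å spacing) — ample for the ~6 Å deep toy pocket.
"""

import numpy as np
import pytest

import gridock as g
from gridock.fieldgrid import DockingCube, GridSet


def make_probe_ligand(charge: float = 1.0):
    """Single-atom charged probe: the simplest dockable ligand."""
    atom = g.AtomRecord(element="N", position=np.zeros(3), partial_charge=charge)
    g.DefaultParameterProvider().assign([atom])
    atom.partial_charge = charge
    topo = g.LigandTopology(atoms=[atom], bonds=[])
    return topo, g.Conformer(np.zeros((1, 3)))


def make_linear_ligand():
    """Two-atom rigid ligand: charged head, apolar tail (1.5 Å bond)."""
    a0 = g.AtomRecord(element="N", position=np.zeros(3), partial_charge=1.0)
    a1 = g.AtomRecord(element="C", position=np.array([1.5, 0.0, 0.0]))
    g.DefaultParameterProvider().assign([a0, a1])
    a0.partial_charge = 1.0
    topo = g.LigandTopology(atoms=[a0, a1], bonds=[g.Bond(0, 1)])
    return topo, g.Conformer(np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]))


@pytest.fixture(scope="session")
def pocket():
    return g.make_toy_pocket(seed=0)


@pytest.fixture(scope="session")
def pocket_cube():
    return DockingCube(center=np.array([0.0, 0.0, -1.0]), edge=10.0, spacing=0.5)


@pytest.fixture(scope="session")
def pocket_grids(pocket, pocket_cube):
    return GridSet.build(pocket, pocket_cube, broadening=0.0)


@pytest.fixture()
def probe_ligand():
    return make_probe_ligand()


@pytest.fixture()
def linear_ligand():
    return make_linear_ligand()
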