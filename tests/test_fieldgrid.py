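"""Grid construction, broadening, trilinear interpolation, persistence."""

import numpy as np
import pytest

import gridock as g
from gridock.energetics import direct_energy, receptor_potential
from gridock.fieldgrid import (
    DockingCube,
    GridSet,
    build_grid,
    grid_energy,
    interpolate,
    load_gridset,
    read_dx,
    save_gridset,
    write_dx,
)
from tests.conftest import make_probe_ligand


@pytest.fixture(scope="module")
def single_atom_receptor():
    atom = g.AtomRecord(element="O", position=np.zeros(3), partial_charge=1.0)
    g.DefaultParameterProvider().assign([atom])
    atom.partial_charge = 1.0
    return g.Receptor(atoms=[atom], site_center=np.zeros(3))


class TestCube:
    def test_node_count_rule(self):
        cube = DockingCube(center=np.zeros(3), edge=22.0, spacing=0.35)
        assert cube.n_nodes == 63  # floor(22/0.35) + 1

    def test_node_coords_span_origin(self):
        cube = DockingCube(center=np.zeros(3), edge=4.0, spacing=1.0)
        nodes = cube.node_coords()
        assert nodes.shape == (125, 3)
        np.testing.assert_allclose(nodes[0], cube.origin)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            DockingCube(center=np.zeros(3), edge=-1.0)


class TestBuildGrid:
    def test_zero_broadening_equals_direct_potential(self, single_atom_receptor):
        cube = DockingCube(center=np.zeros(3), edge=6.0, spacing=1.0)
        lattice = build_grid(single_atom_receptor, cube, "coulomb", broadening=0.0)
        nodes = cube.node_coords()
        direct = np.minimum(
            receptor_potential(single_atom_receptor, nodes, "coulomb"), 1000.0
        ).reshape(lattice.shape)
        np.testing.assert_allclose(lattice, np.maximum(direct, -1000.0))

    def test_coulomb_closed_form_at_node(self, single_atom_receptor):
        # node 3.3211 Å from a unit charge: 332.0716/(3.2711+0.05) ≈ 100 per e
        cube = DockingCube(center=np.array([3.2711, 0, 0]), edge=2.0, spacing=1.0)
        lattice = build_grid(single_atom_receptor, cube, "coulomb", broadening=0.0)
        center_idx = (cube.n_nodes - 1) // 2
        assert lattice[center_idx, center_idx, center_idx] == pytest.approx(
            100.0, abs=0.02
        )

    def test_broadened_below_unbroadened(self, pocket):
        cube = DockingCube(center=np.array([0.0, 0.0, -1.0]), edge=8.0, spacing=1.0)
        plain = build_grid(pocket, cube, "coulomb", broadening=0.0)
        broad = build_grid(pocket, cube, "coulomb", broadening=0.4)
        assert np.all(broad <= plain + 1e-12)

    def test_unknown_probe_requires_params(self, pocket):
        cube = DockingCube(center=np.zeros(3), edge=4.0, spacing=1.0)
        with pytest.raises(ValueError):
            build_grid(pocket, cube, "XX", broadening=0.0)


class TestInterpolate:
    def test_node_values_exact(self, pocket_grids):
        cube = pocket_grids.cube
        node = cube.origin + cube.spacing * np.array([3, 4, 5], dtype=float)
        val = interpolate(pocket_grids.coulomb, cube, node[None, :])[0]
        assert val == pytest.approx(pocket_grids.coulomb[3, 4, 5], abs=1e-9)

    def test_cell_center_is_corner_mean(self):
        cube = DockingCube(center=np.zeros(3), edge=2.0, spacing=1.0)
        rng = np.random.default_rng(1)
        lattice = rng.normal(size=(3, 3, 3))
        center = cube.origin + 0.5
        val = interpolate(lattice, cube, center[None, :])[0]
        assert val == pytest.approx(lattice[:2, :2, :2].mean(), abs=1e-12)

    def test_exact_on_linear_fields(self):
        cube = DockingCube(center=np.zeros(3), edge=4.0, spacing=0.5)
        a, b, c = 1.3, -0.7, 2.1
        nodes = cube.node_coords()
        lattice = (a * nodes[:, 0] + b * nodes[:, 1] + c * nodes[:, 2]).reshape(
            (cube.n_nodes,) * 3
        )
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1.9, 1.9, size=(50, 3))
        vals = interpolate(lattice, cube, pts)
        expected = a * pts[:, 0] + b * pts[:, 1] + c * pts[:, 2]
        np.testing.assert_allclose(vals, expected, atol=1e-10)

    def test_outside_cube_sentinel(self, pocket_grids):
        val = interpolate(
            pocket_grids.coulomb, pocket_grids.cube, np.array([[50.0, 0.0, 0.0]])
        )[0]
        assert val == 1000.0


class TestGridEnergy:
    def test_on_node_equals_direct_sums(self, pocket, pocket_cube, pocket_grids):
        """b=0, ligand atoms exactly on lattice nodes: grid == direct to 1e-9."""
        topo, _ = make_probe_ligand()
        a1 = g.AtomRecord(element="C", position=np.zeros(3))
        g.DefaultParameterProvider().assign([a1])
        topo2 = g.LigandTopology(
            atoms=topo.atoms + [a1], bonds=[g.Bond(0, 1)]
        )
        cube = pocket_cube
        coords = np.array(
            [
                cube.origin + cube.spacing * np.array([8, 9, 4], dtype=float),
                cube.origin + cube.spacing * np.array([11, 9, 4], dtype=float),
            ]
        )
        conf = g.Conformer(coords)
        bd_grid = grid_energy(pocket_grids, topo2, conf)
        bd_direct = direct_energy(pocket, topo2, conf)
        assert bd_grid.e_coulomb == pytest.approx(bd_direct.e_coulomb, abs=1e-9)
        assert bd_grid.e_vdw == pytest.approx(bd_direct.e_vdw, abs=1e-9)
        assert bd_grid.e_pol == pytest.approx(bd_direct.e_pol, abs=1e-9)
        assert bd_grid.e_internal == pytest.approx(bd_direct.e_internal, abs=1e-12)

    def test_off_node_within_half_kcal(self, pocket):
        """At the default 0.35 Å spacing, off-node error stays below 0.5 kcal/mol."""
        topo, conf = make_probe_ligand()
        cube = DockingCube(center=np.array([0.0, 0.0, -1.0]), edge=8.0, spacing=0.35)
        gs = GridSet.build(pocket, cube, broadening=0.0)
        gs.ensure_vdw(topo)
        pose = g.Conformer(np.array([[0.37, -0.22, -3.11]]))
        e_grid = grid_energy(gs, topo, pose).total
        e_direct = direct_energy(pocket, topo, pose).total
        assert abs(e_grid - e_direct) < 0.5

    def test_out_of_cube_atom_penalized(self, pocket_grids):
        topo, conf = make_probe_ligand()
        pose = g.Conformer(np.array([[100.0, 0.0, 0.0]]))
        bd = grid_energy(pocket_grids, topo, pose)
        assert bd.e_coulomb == 1000.0  # q=+1 times the sentinel
        assert bd.e_vdw == 1000.0

    def test_missing_probe_lattice_errors(self, pocket_grids):
        topo, conf = make_probe_ligand()
        stripped = GridSet(
            cube=pocket_grids.cube,
            coulomb=pocket_grids.coulomb,
            desolv=pocket_grids.desolv,
            vdw={},
            receptor=None,
        )
        with pytest.raises(KeyError):
            grid_energy(stripped, topo, conf)


class TestRefinement:
    def test_error_shrinks_as_spacing_halves(self, pocket):
        """Off-node grid error decreases monotonically with lattice refinement."""
        topo, _ = make_probe_ligand()
        pose = g.Conformer(np.array([[0.41, 0.13, -3.37]]))
        e_ref = direct_energy(pocket, topo, pose).total
        errors = []
        for spacing in (1.0, 0.5, 0.25):
            cube = DockingCube(
                center=np.array([0.0, 0.0, -1.0]), edge=8.0, spacing=spacing
            )
            gs = GridSet.build(pocket, cube, broadening=0.0)
            gs.ensure_vdw(topo)
            errors.append(abs(grid_energy(gs, topo, pose).total - e_ref))
        assert errors[0] > errors[1] > errors[2]


class TestPersistence:
    def test_dx_round_trip(self, tmp_path):
        cube = DockingCube(center=np.zeros(3), edge=3.0, spacing=1.0)
        rng = np.random.default_rng(0)
        lattice = rng.normal(size=(4, 4, 4))
        write_dx(tmp_path / "f.dx", lattice, cube)
        back, cube2 = read_dx(tmp_path / "f.dx")
        np.testing.assert_allclose(back, lattice, atol=1e-6)
        np.testing.assert_allclose(cube2.center, cube.center, atol=1e-6)

    def test_gridset_round_trip(self, pocket, tmp_path):
        cube = DockingCube(center=np.array([0.0, 0.0, -1.0]), edge=4.0, spacing=1.0)
        topo, _ = make_probe_ligand()
        gs = GridSet.build(pocket, cube, broadening=0.2)
        gs.ensure_vdw(topo)
        save_gridset(gs, tmp_path / "grids")
        back = load_gridset(tmp_path / "grids")
        np.testing.assert_allclose(back.coulomb, gs.coulomb, atol=1e-5)
        np.testing.assert_allclose(back.vdw["N"], gs.vdw["N"], atol=1e-5)
        assert back.broadening == 0.2
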