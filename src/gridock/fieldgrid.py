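"""Receptor potential grids over the docking cube, with potential broadening.

The receptor is rigid, so its Coulomb, van der Waals (one lattice per
ligand atom type) and desolvation potentials can be tabulated once on a
uniform lattice spanning the docking cube and then evaluated per ligand
atom by trilinear interpolation — the precomputation that makes
genetic-algorithm pose search affordable.

Broadening softens the potentials to mimic small receptor-atom motions
within the rigid-receptor model: each node stores the *minimum* of the
direct potential over a 7-point stencil {x, x ± b·ê} of radius b
(typically 0.3–0.4 Å).  Node values are clamped at +1000 kcal/mol, and the
same +1000 sentinel is returned for points outside the cube so that poses
leaking out of the search region are penalized, not rejected.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemio import Conformer, LigandTopology, Receptor
from .energetics import (
    EnergyBreakdown,
    SolventModel,
    ligand_internal_energy,
    receptor_potential,
)

CLAMP = 1000.0  # kcal/mol, node-value ceiling
OUT_OF_CUBE_PENALTY = 1000.0  # kcal/mol per atom-term outside the cube


@dataclass
class DockingCube:
    """Axis-aligned cubic search region with a uniform lattice."""

    center: np.ndarray
    edge: float = 22.0
    spacing: float = 0.35

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.edge <= 0 or self.spacing <= 0:
            raise ValueError("edge and spacing must be positive")

    @property
    def n_nodes(self) -> int:
        """Nodes per axis: floor(edge/spacing) + 1."""
        return int(math.floor(self.edge / self.spacing + 1e-9)) + 1

    @property
    def origin(self) -> np.ndarray:
        return self.center - self.edge / 2.0

    def node_coords(self) -> np.ndarray:
        """All lattice node positions, shape (n³, 3), x fastest."""
        n = self.n_nodes
        ax = [self.origin[d] + self.spacing * np.arange(n) for d in range(3)]
        gx, gy, gz = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def contains(self, point: np.ndarray) -> bool:
        """True if the point lies within the lattice-covered region."""
        p = np.asarray(point, dtype=float)
        span = (self.n_nodes - 1) * self.spacing
        return bool(np.all(p >= self.origin - 1e-9) and np.all(p <= self.origin + span + 1e-9))


def build_grid(
    receptor: Receptor,
    cube: DockingCube,
    probe: str,
    broadening: float = 0.35,
    solvent: SolventModel | None = None,
    probe_vdw: tuple[float, float] | None = None,
) -> np.ndarray:
    """Tabulate one receptor potential on the cube lattice.

    ``probe`` as in :func:`gridock.energetics.receptor_potential`.  Each
    node takes the minimum of the direct potential over the 7-point
    broadening stencil; b = 0 degenerates to the plain node potential.
    Values are clamped symmetrically to ±1000 kcal/mol — the lower clamp
    tames the Coulomb singularity at nodes that coincide with a charged
    receptor atom.
    """
    if not receptor.atoms:
        raise ValueError("receptor must be nonempty")
    if broadening < 0:
        raise ValueError("broadening must be >= 0")
    nodes = cube.node_coords()
    n = cube.n_nodes
    if broadening == 0.0:
        vals = receptor_potential(receptor, nodes, probe, solvent, probe_vdw)
    else:
        offsets = np.concatenate(
            [np.zeros((1, 3)), broadening * np.eye(3), -broadening * np.eye(3)]
        )
        vals = np.full(nodes.shape[0], np.inf)
        for off in offsets:
            vals = np.minimum(
                vals,
                receptor_potential(receptor, nodes + off, probe, solvent, probe_vdw),
            )
    vals = np.clip(vals, -CLAMP, CLAMP)
    return vals.reshape(n, n, n)


@dataclass
class GridSet:
    """A receptor's full grid stack: Coulomb, desolvation, per-type vdW."""

    cube: DockingCube
    coulomb: np.ndarray
    desolv: np.ndarray
    vdw: dict[str, np.ndarray] = field(default_factory=dict)
    broadening: float = 0.35
    solvent: SolventModel = field(default_factory=SolventModel)
    receptor: Receptor | None = None  # kept for lazy vdW lattice builds

    @classmethod
    def build(
        cls,
        receptor: Receptor,
        cube: DockingCube,
        ligand_types: dict[str, tuple[float, float]] | None = None,
        broadening: float = 0.35,
        solvent: SolventModel | None = None,
    ) -> "GridSet":
        solvent = solvent or SolventModel()
        gs = cls(
            cube=cube,
            coulomb=build_grid(receptor, cube, "coulomb", broadening, solvent),
            desolv=build_grid(receptor, cube, "desolv", broadening, solvent),
            broadening=broadening,
            solvent=solvent,
            receptor=receptor,
        )
        for t, (eps, rstar) in (ligand_types or {}).items():
            gs.vdw[t] = build_grid(
                receptor, cube, t, broadening, solvent, probe_vdw=(eps, rstar)
            )
        return gs

    def ensure_vdw(self, topology: LigandTopology) -> None:
        """Build (lazily) vdW lattices for every ligand atom type."""
        for a in topology.atoms:
            if a.ff_type not in self.vdw:
                if self.receptor is None:
                    raise KeyError(
                        f"no vdW lattice for type {a.ff_type!r} and no receptor "
                        "to build one from"
                    )
                self.vdw[a.ff_type] = build_grid(
                    self.receptor,
                    self.cube,
                    a.ff_type,
                    self.broadening,
                    self.solvent,
                    probe_vdw=(a.vdw_eps, a.vdw_rstar),
                )


def interpolate(
    lattice: np.ndarray, cube: DockingCube, points: np.ndarray
) -> np.ndarray:
    """Trilinear interpolation of a lattice at arbitrary points.

    Points outside the cube get the +1000 kcal/mol sentinel.  Exact on
    lattice nodes and on any field linear in the coordinates.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = cube.n_nodes
    u = (pts - cube.origin[None, :]) / cube.spacing
    inside = np.all((u >= -1e-9) & (u <= n - 1 + 1e-9), axis=1)
    u = np.clip(u, 0.0, n - 1 - 1e-12)
    i0 = np.minimum(u.astype(int), n - 2)
    frac = u - i0
    out = np.full(pts.shape[0], OUT_OF_CUBE_PENALTY)
    if np.any(inside):
        ii = i0[inside]
        f = frac[inside]
        acc = np.zeros(ii.shape[0])
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1.0 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1.0 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1.0 - f[:, 2]
                    acc += (
                        wx
                        * wy
                        * wz
                        * lattice[ii[:, 0] + dx, ii[:, 1] + dy, ii[:, 2] + dz]
                    )
        out[inside] = acc
    return out if np.asarray(points).ndim == 2 else out


def grid_energy(
    grids: GridSet, topology: LigandTopology, conformer: Conformer
) -> EnergyBreakdown:
    """Grid-interpolated protein–ligand energy plus exact internal energy.

    e_coulomb = Σ qᵢ·C(xᵢ); e_vdw = Σ V_type(xᵢ); e_pol = Σ qᵢ²·D(xᵢ);
    e_internal is evaluated gridlessly (it does not involve the receptor).
    """
    grids.ensure_vdw(topology)
    x = conformer.coords
    q = topology.charges()
    e_c = float(np.sum(q * interpolate(grids.coulomb, grids.cube, x)))
    e_p = float(np.sum(q**2 * interpolate(grids.desolv, grids.cube, x)))
    e_v = 0.0
    for k, a in enumerate(topology.atoms):
        e_v += float(interpolate(grids.vdw[a.ff_type], grids.cube, x[k : k + 1])[0])
    e_i = ligand_internal_energy(topology, conformer, grids.solvent)
    return EnergyBreakdown(e_coulomb=e_c, e_vdw=e_v, e_pol=e_p, e_internal=e_i)


# ---------------------------------------------------------------------------
# persistence: OpenDX scalar fields + JSON manifest


def write_dx(path: str | Path, lattice: np.ndarray, cube: DockingCube) -> None:
    """Write one lattice as an OpenDX regular scalar field (text)."""
    n = cube.n_nodes
    o = cube.origin
    s = cube.spacing
    lines = [
        f"object 1 class gridpositions counts {n} {n} {n}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {s:.6f} 0.0 0.0",
        f"delta 0.0 {s:.6f} 0.0",
        f"delta 0.0 0.0 {s:.6f}",
        f"object 2 class gridconnections counts {n} {n} {n}",
        f"object 3 class array type double rank 0 items {n**3} data follows",
    ]
    flat = lattice.ravel()
    for k in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.10e}" for v in flat[k : k + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> tuple[np.ndarray, DockingCube]:
    """Read a lattice written by :func:`write_dx`."""
    counts = None
    origin = None
    deltas = []
    values: list[float] = []
    in_data = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("object 1"):
            counts = [int(v) for v in line.split()[-3:]]
        elif line.startswith("origin"):
            origin = np.array([float(v) for v in line.split()[1:4]])
        elif line.startswith("delta"):
            deltas.append([float(v) for v in line.split()[1:4]])
        elif "data follows" in line:
            in_data = True
        elif line.startswith("attribute"):
            in_data = False
        elif in_data and line:
            values.extend(float(v) for v in line.split())
    if counts is None or origin is None or not deltas:
        raise ValueError(f"{path}: not a recognized DX scalar field")
    n = counts[0]
    spacing = deltas[0][0]
    edge = (n - 1) * spacing
    cube = DockingCube(center=origin + edge / 2.0, edge=edge, spacing=spacing)
    return np.array(values).reshape(n, n, n), cube


def receptor_checksum(receptor: Receptor) -> str:
    h = hashlib.sha256()
    h.update(receptor.coords.tobytes())
    h.update(receptor.charges().tobytes())
    return h.hexdigest()[:16]


def save_gridset(grids: GridSet, outdir: str | Path) -> None:
    """Persist a GridSet: one DX file per lattice plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dx(outdir / "coulomb.dx", grids.coulomb, grids.cube)
    write_dx(outdir / "desolv.dx", grids.desolv, grids.cube)
    for t, lat in grids.vdw.items():
        write_dx(outdir / f"vdw_{t}.dx", lat, grids.cube)
    manifest = {
        "center": grids.cube.center.tolist(),
        "edge": grids.cube.edge,
        "spacing": grids.cube.spacing,
        "broadening": grids.broadening,
        "eps_in": grids.solvent.eps_in,
        "eps_out": grids.solvent.eps_out,
        "vdw_types": sorted(grids.vdw),
        "receptor_checksum": (
            receptor_checksum(grids.receptor) if grids.receptor else None
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_gridset(indir: str | Path) -> GridSet:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    cube = DockingCube(
        center=np.array(manifest["center"]),
        edge=manifest["edge"],
        spacing=manifest["spacing"],
    )
    coulomb, _ = read_dx(indir / "coulomb.dx")
    desolv, _ = read_dx(indir / "desolv.dx")
    vdw = {t: read_dx(indir / f"vdw_{t}.dx")[0] for t in manifest["vdw_types"]}
    return GridSet(
        cube=cube,
        coulomb=coulomb,
        desolv=desolv,
        vdw=vdw,
        broadening=manifest["broadening"],
        solvent=SolventModel(
            eps_in=manifest["eps_in"], eps_out=manifest["eps_out"]
        ),
    )
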