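"""Molecular structure I/O, synthetic fixtures, and force-field parameter assignment.

This module owns the in-memory containers used throughout the package
(:class:`AtomRecord`, :class:`Receptor`, :class:`LigandTopology`,
:class:`Conformer`, :class:`ActivityRecord`), reads receptors from PDB and
ligands from SDF/MOL2, detects rotatable torsions, and generates the
synthetic pocket/ligand fixtures every other module is tested against.

Receptor structures are assumed pre-protonated; no hydrogen addition is
performed here.  Force-field parameters (partial charge, van der Waals
well depth and radius, Born radius, mass) are supplied through a pluggable
:class:`ParameterProvider`; the default provider ships a small per-element
table adequate for the synthetic fixtures and generic organic molecules.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal/(mol K)

# per-element (vdw_eps kcal/mol, vdw_rstar Å, born_radius Å, mass amu);
# rstar combines by arithmetic mean between atoms, eps by geometric mean
_ELEMENT_TABLE: dict[str, tuple[float, float, float, float]] = {
    "H": (0.022, 2.40, 1.20, 1.008),
    "C": (0.070, 3.90, 1.70, 12.011),
    "N": (0.110, 3.60, 1.55, 14.007),
    "O": (0.120, 3.50, 1.50, 15.999),
    "F": (0.080, 3.30, 1.47, 18.998),
    "P": (0.200, 4.20, 1.85, 30.974),
    "S": (0.250, 4.10, 1.80, 32.06),
    "CL": (0.280, 3.90, 1.75, 35.45),
    "BR": (0.380, 4.10, 1.85, 79.904),
    "I": (0.500, 4.30, 1.98, 126.904),
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid structure."""


@dataclass
class AtomRecord:
    """One typed, parameterized atom.

    Coordinates are in Å; ``partial_charge`` in elementary charges;
    ``vdw_eps`` in kcal/mol; ``vdw_rstar`` and ``born_radius`` in Å.
    """

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    ff_type: str = ""
    vdw_eps: float = 0.0
    vdw_rstar: float = 1.0
    born_radius: float = 1.5

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be 3 finite coordinates")
        if self.vdw_eps < 0:
            raise ValueError("vdw_eps must be >= 0")
        if self.vdw_rstar <= 0:
            raise ValueError("vdw_rstar must be > 0")
        if self.born_radius <= 0:
            raise ValueError("born_radius must be > 0")

    @property
    def mass(self) -> float:
        entry = _ELEMENT_TABLE.get(self.element.upper())
        return entry[3] if entry else 12.011

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Receptor:
    """A rigid, parameterized receptor: atoms never move downstream."""

    atoms: list[AtomRecord]
    site_center: np.ndarray

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("receptor must contain at least one atom")
        self.site_center = np.asarray(self.site_center, dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float = 1.0
    in_ring: bool = False

    def other(self, k: int) -> int:
        return self.j if k == self.i else self.i


@dataclass(frozen=True)
class Torsion:
    """A rotatable torsion: rotation of ``moving`` atoms about bond a–b."""

    a: int
    b: int
    moving: frozenset[int]
    quadruple: tuple[int, int, int, int]


@dataclass
class LigandTopology:
    """Ligand connectivity and parameters; coordinates live in Conformer."""

    atoms: list[AtomRecord]
    bonds: list[Bond]
    rotatable_torsions: list[Torsion] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            k = stack.pop()
            for m in adj[k]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        if n and len(seen) != n:
            raise ValueError("ligand bond graph must be connected")

    @property
    def n_tors(self) -> int:
        return len(self.rotatable_torsions)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def graph_distances(self) -> np.ndarray:
        """All-pairs bond-count distances (BFS per atom)."""
        n = self.n_atoms
        adj = self.adjacency()
        dist = np.full((n, n), n + 1, dtype=int)
        for s in range(n):
            dist[s, s] = 0
            queue = [s]
            while queue:
                nxt = []
                for k in queue:
                    for m in adj[k]:
                        if dist[s, m] > dist[s, k] + 1:
                            dist[s, m] = dist[s, k] + 1
                            nxt.append(m)
                queue = nxt
        return dist

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])


@dataclass
class Conformer:
    """Cartesian coordinates (Å), one row per topology atom."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("conformer coordinates must be (n, 3)")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformer":
        return Conformer(self.coords.copy())


@dataclass
class ActivityRecord:
    """Experimental activity: inhibition constant and derived free energy."""

    ligand_id: str
    ki: float  # molar
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise ValueError("Ki must be positive")

    @property
    def dg_exp(self) -> float:
        """Binding free energy ΔG = RT·ln(Ki), kcal/mol."""
        return GAS_CONSTANT_KCAL * self.temperature * math.log(self.ki)


# ---------------------------------------------------------------------------
# parameter assignment


class ParameterProvider:
    """Contract for force-field parameter assignment.

    Implementations fill ``ff_type``, ``vdw_eps``, ``vdw_rstar`` and
    ``born_radius`` on atoms in place; charges are only overwritten when the
    provider knows better than the source file.
    """

    def assign(self, atoms: Sequence[AtomRecord]) -> None:  # pragma: no cover
        raise NotImplementedError


class DefaultParameterProvider(ParameterProvider):
    """Per-element lookup table; unknown elements fall back to carbon."""

    def assign(self, atoms: Sequence[AtomRecord]) -> None:
        for a in atoms:
            key = a.element.upper()
            eps, rstar, born, _mass = _ELEMENT_TABLE.get(
                key, _ELEMENT_TABLE["C"]
            )
            a.ff_type = a.ff_type or key
            a.vdw_eps = eps
            a.vdw_rstar = rstar
            a.born_radius = born


# ---------------------------------------------------------------------------
# torsion detection


def count_rotatable_torsions(topology: LigandTopology) -> int:
    """Number of rotatable torsions: single acyclic bonds rotating heavy atoms.

    A bond qualifies when it is a non-ring single bond and each end atom has
    at least one additional heavy-atom neighbour (terminal bonds rotate no
    heavy atoms and do not count).  Amide and conjugated single bonds count
    unless they sit in a ring.
    """
    return len(detect_rotatable_torsions(topology.atoms, topology.bonds))


def detect_rotatable_torsions(
    atoms: Sequence[AtomRecord], bonds: Sequence[Bond]
) -> list[Torsion]:
    adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for b in bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)

    def heavy_neighbors(k: int, excl: int) -> list[int]:
        return [m for m in adj[k] if m != excl and atoms[m].is_heavy]

    torsions: list[Torsion] = []
    for b in bonds:
        if b.in_ring or b.order != 1.0:
            continue
        hi = heavy_neighbors(b.i, b.j)
        hj = heavy_neighbors(b.j, b.i)
        if not hi or not hj:
            continue
        moving = _side_atoms(adj, b.j, b.i)
        torsions.append(
            Torsion(
                a=b.i,
                b=b.j,
                moving=frozenset(moving),
                quadruple=(min(hi), b.i, b.j, min(hj)),
            )
        )
    return torsions


def _side_atoms(adj: dict[int, list[int]], start: int, blocked: int) -> set[int]:
    """Atoms reachable from ``start`` without crossing the start–blocked bond."""
    seen = {start}
    stack = [start]
    while stack:
        k = stack.pop()
        for m in adj[k]:
            if k == start and m == blocked:
                continue
            if m not in seen:
                seen.add(m)
                stack.append(m)
    seen.discard(start)
    return seen


# ---------------------------------------------------------------------------
# readers / writers


def read_receptor(
    path: str | Path, provider: ParameterProvider | None = None
) -> Receptor:
    """Read a pre-protonated receptor from a PDB file.

    First model only; altLoc other than blank/'A' dropped; waters dropped;
    atoms kept in file order. The site center defaults to the geometric
    center of the kept atoms (override by constructing a new Receptor).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    provider = provider or DefaultParameterProvider()
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            structure = PDBParser(QUIET=True).get_structure("receptor", str(path))
    except Exception as exc:
        raise FormatError(f"{path}: unparseable PDB: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no usable ATOM/HETATM records")
    atoms: list[AtomRecord] = []
    for residue in models[0].get_residues():  # first model only
        if residue.get_resname().strip() in ("HOH", "WAT", "DOD"):
            continue
        for atom in residue.get_unpacked_list():
            if atom.get_altloc().strip() not in ("", "A"):
                continue
            element = (atom.element or atom.get_name()[:1]).strip()
            if element.upper() not in _ELEMENT_TABLE:
                log.warning("skipping atom with unknown element %r", element)
                continue
            coord = atom.get_coord()
            if coord is None or not np.all(np.isfinite(coord)):
                raise FormatError(f"{path}: atom {atom.get_full_id()} lacks coordinates")
            atoms.append(
                AtomRecord(element=element.capitalize(), position=np.asarray(coord, float))
            )
    if not atoms:
        raise FormatError(f"{path}: no usable ATOM/HETATM records")
    provider.assign(atoms)
    center = np.mean([a.position for a in atoms], axis=0)
    return Receptor(atoms=atoms, site_center=center)


def read_ligand(
    path: str | Path, provider: ParameterProvider | None = None
) -> tuple[LigandTopology, Conformer]:
    """Read a single 3D molecule from SDF or MOL2 via RDKit.

    Bonds, ring flags and rotatable torsions are populated; Gasteiger
    partial charges are computed; other parameters come from the provider.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".mol", ".sd"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise FormatError(f"{path}: no parseable molecule")
        if len(mols) > 1:
            raise FormatError(
                f"{path}: multiple molecules; use read_ligands() for libraries"
            )
        mol = mols[0]
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
        if mol is None:
            raise FormatError(f"{path}: unparseable MOL2")
    else:
        raise FormatError(f"{path}: unsupported ligand format {suffix!r}")
    return _mol_to_ligand(mol, provider)


def read_ligands(
    path: str | Path, provider: ParameterProvider | None = None
) -> Iterable[tuple[str, LigandTopology, Conformer]]:
    """Iterate (name, topology, conformer) over a multi-record SDF.

    Unparseable records are skipped with a warning, never abort the run.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"{path}: skipping unparseable record {idx}")
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
        try:
            topo, conf = _mol_to_ligand(mol, provider)
        except FormatError as exc:
            warnings.warn(f"{path}: skipping record {idx}: {exc}")
            continue
        yield name or f"mol{idx}", topo, conf


def _mol_to_ligand(
    mol, provider: ParameterProvider | None
) -> tuple[LigandTopology, Conformer]:
    from rdkit.Chem import AllChem

    provider = provider or DefaultParameterProvider()
    if mol.GetNumConformers() == 0:
        raise FormatError("molecule has no coordinates")
    conf = mol.GetConformer()
    if not conf.Is3D():
        raise FormatError("molecule has 2D-only coordinates; 3D required")
    AllChem.ComputeGasteigerCharges(mol)
    coords = conf.GetPositions()
    atoms = []
    for a in mol.GetAtoms():
        q = float(a.GetDoubleProp("_GasteigerCharge"))
        if not math.isfinite(q):
            q = float(a.GetFormalCharge())
        atoms.append(
            AtomRecord(
                element=a.GetSymbol(),
                position=coords[a.GetIdx()],
                partial_charge=q,
            )
        )
    provider.assign(atoms)
    bonds = [
        Bond(
            i=b.GetBeginAtomIdx(),
            j=b.GetEndAtomIdx(),
            order=float(b.GetBondTypeAsDouble()),
            in_ring=b.IsInRing(),
        )
        for b in mol.GetBonds()
    ]
    torsions = detect_rotatable_torsions(atoms, bonds)
    topo = LigandTopology(atoms=atoms, bonds=bonds, rotatable_torsions=torsions)
    return topo, Conformer(coords)


def write_ligand_sdf(
    path: str | Path,
    topology: LigandTopology,
    conformers: Conformer | Sequence[Conformer],
    name: str = "ligand",
    properties: Sequence[dict] | None = None,
) -> None:
    """Write one or more conformers of a ligand as (multi-record) SDF."""
    from rdkit import Chem
    from rdkit.Chem import RWMol
    from rdkit.Geometry import Point3D

    if isinstance(conformers, Conformer):
        conformers = [conformers]
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    writer = Chem.SDWriter(str(path))
    try:
        for rec_idx, cf in enumerate(conformers):
            rw = RWMol()
            for a in topology.atoms:
                at = Chem.Atom(a.element)
                at.SetNoImplicit(True)
                rw.AddAtom(at)
            for b in topology.bonds:
                rw.AddBond(b.i, b.j, order_map.get(b.order, Chem.BondType.SINGLE))
            mol = rw.GetMol()
            Chem.SanitizeMol(
                mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS, catchErrors=True
            )
            rdconf = Chem.Conformer(topology.n_atoms)
            for k, xyz in enumerate(cf.coords):
                rdconf.SetAtomPosition(k, Point3D(*map(float, xyz)))
            mol.AddConformer(rdconf)
            mol.SetProp("_Name", name if len(conformers) == 1 else f"{name}_{rec_idx}")
            if properties and rec_idx < len(properties):
                for key, val in properties[rec_idx].items():
                    mol.SetProp(str(key), str(val))
            writer.write(mol)
    finally:
        writer.close()


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read an activity table: columns id, ki_molar[, temperature_K]."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                ActivityRecord(
                    ligand_id=row["id"],
                    ki=float(row["ki_molar"]),
                    temperature=float(row.get("temperature_K") or 298.15),
                )
            )
    return records


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_toy_pocket(
    n_shell_atoms: int = 24, charge_at_base: float = -1.0, seed: int = 0
) -> Receptor:
    """Synthetic binding pocket: an apolar hemispherical shell with one
    charged atom at its base.

    Emulates the geometry of a primary specificity pocket of a trypsin-like
    protease: a mostly hydrophobic cavity ~6 Å deep with a charged anchor
    (an aspartate-like carboxylate) at the bottom that pairs with cationic
    ligand groups.  The cavity opens toward +z; ``site_center`` sits at the
    cavity mouth.  Deterministic for a given (parameters, seed).
    """
    if n_shell_atoms < 8:
        raise ValueError("n_shell_atoms must be >= 8")
    rng = np.random.default_rng(seed)
    radius = 6.0
    atoms: list[AtomRecord] = []
    # golden-spiral points on the lower hemisphere (z <= 0), jittered slightly
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for k in range(n_shell_atoms):
        z = -(k + 0.5) / n_shell_atoms  # in (-1, 0)
        rho = math.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * k
        p = radius * np.array([rho * math.cos(phi), rho * math.sin(phi), z])
        p = p + rng.normal(0.0, 0.05, size=3)
        atoms.append(AtomRecord(element="C", position=p))
    # charged anchor at the cavity base, slightly recessed
    atoms.append(
        AtomRecord(
            element="O",
            position=np.array([0.0, 0.0, -radius]),
            partial_charge=float(charge_at_base),
        )
    )
    DefaultParameterProvider().assign(atoms)
    atoms[-1].partial_charge = float(charge_at_base)
    return Receptor(atoms=atoms, site_center=np.array([0.0, 0.0, 2.0]))


def make_toy_ligand(
    n_torsions: int = 2, seed: int = 0
) -> tuple[LigandTopology, Conformer]:
    """Synthetic ligand: a heavy-atom chain with a charged head group.

    The chain has ``n_torsions + 3`` carbon-like atoms (bond length 1.5 Å,
    angle ~112°), so exactly ``n_torsions`` internal single bonds rotate
    heavy atoms; the first atom carries charge +1 (an amidinium-like head
    that the toy pocket's anchor attracts).  Torsion angles are randomized
    per seed; topology is independent of the seed.
    """
    if not 0 <= n_torsions <= 12:
        raise ValueError("n_torsions must be in [0, 12]")
    n = n_torsions + 3
    rng = np.random.default_rng(seed)
    bond, angle = 1.5, math.radians(112.0)
    # planar zigzag: consecutive bond vectors (s, ±c) give bond angle `angle`
    s = bond * math.sin(angle / 2.0)
    c = bond * math.cos(angle / 2.0)
    coords = np.array([[k * s, (k % 2) * c, 0.0] for k in range(n)])
    atoms = [
        AtomRecord(element=("N" if k == 0 else "C"), position=coords[k])
        for k in range(n)
    ]
    atoms[0].partial_charge = 1.0
    DefaultParameterProvider().assign(atoms)
    atoms[0].partial_charge = 1.0
    bonds = [Bond(i=k, j=k + 1, order=1.0, in_ring=False) for k in range(n - 1)]
    torsions = detect_rotatable_torsions(atoms, bonds)
    topo = LigandTopology(atoms=atoms, bonds=bonds, rotatable_torsions=torsions)
    cf = Conformer(coords)
    if torsions:
        from .gadock import apply_torsions  # local import: avoids cycle at load

        angles = rng.uniform(-math.pi, math.pi, size=len(torsions))
        cf = apply_torsions(topo, cf, angles)
    assert count_rotatable_torsions(topo) == n_torsions
    return topo, cf
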