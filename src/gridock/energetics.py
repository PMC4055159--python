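"""Pairwise protein–ligand and intra-ligand energy terms with implicit solvent.

Functional forms follow the MMFF94 conventions for nonbonded interactions:
buffered Coulomb electrostatics (0.05 Å buffer, 332.0716 kcal·Å/(mol·e²))
and the buffered-14-7 van der Waals potential.  Polar desolvation uses the
Still pairwise generalized-Born (GB) form with fixed per-type Born radii;
nonpolar desolvation is a surface-area term (γ × buried solvent-accessible
area, probe 1.4 Å, two-sphere cap approximation).

Ligand bond lengths and angles are treated as rigid throughout the
package, so the intramolecular energy keeps only torsional terms and
nonbonded interactions between atoms more than three bonds apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemio import AtomRecord, Conformer, LigandTopology, Receptor

COULOMB_K = 332.0716  # kcal·Å/(mol·e²)
COULOMB_BUFFER = 0.05  # Å, MMFF buffered electrostatics
GB_K = COULOMB_K / 2.0  # 166.0358; the "166" prefactor of the Born equation
PROBE_RADIUS = 1.4  # Å, water probe for SASA
TORSION_BARRIER = 1.4  # kcal/mol, 3-fold barrier height for generic torsions


@dataclass
class SolventModel:
    """Continuum-solvent parameters for the GB/SA desolvation terms."""

    eps_in: float = 1.0
    eps_out: float = 80.0
    gamma_np: float = 0.0072  # kcal/(mol·Å²)
    gb_smoothing: float = 0.0  # Å, reserved for smoothed-dielectric variants

    def __post_init__(self) -> None:
        if not self.eps_out > self.eps_in >= 1.0:
            raise ValueError("require eps_out > eps_in >= 1")

    @property
    def polarity_factor(self) -> float:
        """(1/ε_in − 1/ε_out), the GB solvent-polarity prefactor."""
        return 1.0 / self.eps_in - 1.0 / self.eps_out


@dataclass
class EnergyBreakdown:
    """Component-wise energies, kcal/mol.  ``total`` is their sum."""

    e_coulomb: float = 0.0
    e_vdw: float = 0.0
    e_pol: float = 0.0
    e_np: float = 0.0
    e_internal: float = 0.0

    @property
    def total(self) -> float:
        return self.e_coulomb + self.e_vdw + self.e_pol + self.e_np + self.e_internal


# ---------------------------------------------------------------------------
# pair potentials


def pair_coulomb(qi: float, qj: float, r: float, eps_in: float = 1.0) -> float:
    """Buffered Coulomb interaction, kcal/mol: 332.0716·qi·qj/(ε·(r+0.05))."""
    if r <= 0:
        raise ValueError("distance must be positive")
    return COULOMB_K * qi * qj / (eps_in * (r + COULOMB_BUFFER))


def pair_vdw(eps_ij: float, rstar_ij: float, r: float) -> float:
    """Buffered-14-7 van der Waals interaction, kcal/mol.

    ε_ij·(1.07R*/(r+0.07R*))⁷·(1.12R*⁷/(r⁷+0.12R*⁷) − 2); the minimum is
    exactly −ε_ij at r = R*.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    rs7 = rstar_ij**7
    a = (1.07 * rstar_ij / (r + 0.07 * rstar_ij)) ** 7
    b = 1.12 * rs7 / (r**7 + 0.12 * rs7) - 2.0
    return eps_ij * a * b


def combine_vdw(a: AtomRecord, b: AtomRecord) -> tuple[float, float]:
    """Combination rules: geometric-mean well depth, arithmetic-mean R*."""
    return math.sqrt(a.vdw_eps * b.vdw_eps), 0.5 * (a.vdw_rstar + b.vdw_rstar)


def _pair_vdw_arrays(eps: np.ndarray, rstar: np.ndarray, r: np.ndarray) -> np.ndarray:
    rs7 = rstar**7
    a = (1.07 * rstar / (r + 0.07 * rstar)) ** 7
    b = 1.12 * rs7 / (r**7 + 0.12 * rs7) - 2.0
    return eps * a * b


# ---------------------------------------------------------------------------
# generalized Born polar desolvation


def f_gb(r: np.ndarray, ai: np.ndarray, aj: np.ndarray) -> np.ndarray:
    """Still interpolation: sqrt(r² + aᵢaⱼ·exp(−r²/(4aᵢaⱼ)))."""
    prod = ai * aj
    return np.sqrt(r * r + prod * np.exp(-(r * r) / (4.0 * prod)))


def gb_polar_desolvation(
    atoms: list[AtomRecord], solvent: SolventModel | None = None
) -> float:
    """Still-type pairwise GB solvation free energy of a charged atom set.

    ΔG = −166·(1/ε_in − 1/ε_out)·Σᵢⱼ qᵢqⱼ/f_GB(rᵢⱼ,aᵢ,aⱼ), the sum running
    over all ordered pairs including the self terms (f_GB(0) = aᵢ), so a
    single charge recovers the Born equation −166·(1/ε_in − 1/ε_out)·q²/a.
    """
    solvent = solvent or SolventModel()
    q = np.array([a.partial_charge for a in atoms])
    born = np.array([a.born_radius for a in atoms])
    if np.any(born <= 0):
        raise ValueError("Born radii must be positive")
    x = np.array([a.position for a in atoms])
    r = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    f = f_gb(r, born[:, None], born[None, :])
    return float(-GB_K * solvent.polarity_factor * np.sum(np.outer(q, q) / f))


def born_desolvation_field(
    receptor: Receptor,
    points: np.ndarray,
    probe_born_radius: float = 1.6,
    solvent: SolventModel | None = None,
) -> np.ndarray:
    """Per-unit-charge² polar desolvation penalty of a probe near the receptor.

    The probe's effective Born radius grows as receptor atoms descreen it,
    1/a_eff(x) = 1/a₀ − Σⱼ ρⱼ/(2·rⱼ²) (clamped ≥ 1/(10a₀)), and the penalty
    is the loss of Born self-energy, 166·(1/ε_in − 1/ε_out)·(1/a₀ − 1/a_eff).
    Quadratic in probe charge; ≥ 0; → 0 far from the receptor.
    """
    solvent = solvent or SolventModel()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rx = receptor.coords
    rho = np.array([a.born_radius for a in receptor.atoms])
    inv_a0 = 1.0 / probe_born_radius
    out = np.empty(points.shape[0])
    for chunk in range(0, points.shape[0], 4096):
        pts = points[chunk : chunk + 4096]
        d2 = np.sum((pts[:, None, :] - rx[None, :, :]) ** 2, axis=-1)
        d2 = np.maximum(d2, 1.0)  # descreening saturates inside atomic cores
        inv_aeff = inv_a0 - 0.5 * np.sum(rho[None, :] / d2, axis=1)
        inv_aeff = np.clip(inv_aeff, 0.1 * inv_a0, inv_a0)
        out[chunk : chunk + 4096] = (
            GB_K * solvent.polarity_factor * (inv_a0 - inv_aeff)
        )
    return out


# ---------------------------------------------------------------------------
# nonpolar desolvation (buried surface area)


def buried_area(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
    probe: float = PROBE_RADIUS,
) -> float:
    """Solvent-accessible area of set A buried by set B (pairwise caps, Å²).

    For each sphere pair the buried patch on A is the exact spherical cap
    cut by the intersection with B's solvent-expanded sphere; caps are
    summed without multi-body overlap correction (pairwise approximation).
    """
    ra = radii_a + probe
    rb = radii_b + probe
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
    d = np.maximum(d, 1e-9)
    overlap = d < (ra[:, None] + rb[None, :])
    # cap height on sphere A from sphere-sphere intersection geometry
    h = ra[:, None] - (d / 2.0 + (ra[:, None] ** 2 - rb[None, :] ** 2) / (2.0 * d))
    h = np.clip(h, 0.0, 2.0 * ra[:, None])
    caps = 2.0 * math.pi * ra[:, None] * h * overlap
    per_atom = np.minimum(caps.sum(axis=1), 4.0 * math.pi * ra**2)
    return float(per_atom.sum())


def nonpolar_desolvation(
    receptor: Receptor,
    topology: LigandTopology,
    conformer: Conformer,
    solvent: SolventModel | None = None,
) -> float:
    """γ_np × intermolecular buried SASA (both partners), kcal/mol."""
    solvent = solvent or SolventModel()
    if solvent.gamma_np == 0.0:
        return 0.0
    lx = conformer.coords
    lr = np.array([0.5 * a.vdw_rstar for a in topology.atoms])
    rx = receptor.coords
    rr = np.array([0.5 * a.vdw_rstar for a in receptor.atoms])
    buried = buried_area(lx, lr, rx, rr) + buried_area(rx, rr, lx, lr)
    return solvent.gamma_np * buried


# ---------------------------------------------------------------------------
# intramolecular energy


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (radians) of four points, IUPAC sign convention."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(float(np.dot(m, n2)), float(np.dot(n1, n2)))


def ligand_internal_energy(
    topology: LigandTopology,
    conformer: Conformer,
    solvent: SolventModel | None = None,
    torsion_barrier: float = TORSION_BARRIER,
) -> float:
    """Intramolecular strain-relevant energy, kcal/mol.

    Sum of a generic 3-fold torsion term V₃/2·(1+cos 3φ) over the rotatable
    torsions plus nonbonded (Coulomb + buffered-14-7) interactions between
    atom pairs more than three bonds apart.  Bond and angle terms are
    omitted by construction: the internal geometry is rigid apart from
    torsions, so they are constant.  Invariant under rigid motion.
    """
    if conformer.n_atoms != topology.n_atoms:
        raise ValueError("conformer/topology atom count mismatch")
    solvent = solvent or SolventModel()
    x = conformer.coords
    energy = 0.0
    for t in topology.rotatable_torsions:
        i, a, b, j = t.quadruple
        phi = dihedral_angle(x[i], x[a], x[b], x[j])
        energy += 0.5 * torsion_barrier * (1.0 + math.cos(3.0 * phi))
    dist = topology.graph_distances()
    n = topology.n_atoms
    for i in range(n):
        ai = topology.atoms[i]
        for j in range(i + 1, n):
            if dist[i, j] <= 3:
                continue
            aj = topology.atoms[j]
            r = float(np.linalg.norm(x[i] - x[j]))
            energy += pair_coulomb(
                ai.partial_charge, aj.partial_charge, r, solvent.eps_in
            )
            eps, rstar = combine_vdw(ai, aj)
            energy += pair_vdw(eps, rstar, r)
    return energy


# ---------------------------------------------------------------------------
# receptor potentials and direct (gridless) docking energy


def receptor_potential(
    receptor: Receptor,
    points: np.ndarray,
    probe: str,
    solvent: SolventModel | None = None,
    probe_vdw: tuple[float, float] | None = None,
) -> np.ndarray:
    """Receptor potential at arbitrary points for one probe species.

    ``probe`` is ``'coulomb'`` (kcal/(mol·e)), ``'desolv'``
    (kcal/mol per unit charge²) or a van der Waals probe for which
    ``probe_vdw = (eps, rstar)`` must be given (kcal/mol).
    """
    solvent = solvent or SolventModel()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if probe == "desolv":
        return born_desolvation_field(receptor, points, solvent=solvent)
    rx = receptor.coords
    out = np.zeros(points.shape[0])
    if probe == "coulomb":
        q = receptor.charges()
        for chunk in range(0, points.shape[0], 4096):
            pts = points[chunk : chunk + 4096]
            r = np.linalg.norm(pts[:, None, :] - rx[None, :, :], axis=-1)
            out[chunk : chunk + 4096] = np.sum(
                COULOMB_K * q[None, :] / (solvent.eps_in * (r + COULOMB_BUFFER)),
                axis=1,
            )
        return out
    if probe_vdw is None:
        raise ValueError(f"probe {probe!r} requires probe_vdw=(eps, rstar)")
    p_eps, p_rstar = probe_vdw
    eps = np.array([math.sqrt(p_eps * a.vdw_eps) for a in receptor.atoms])
    rstar = np.array([0.5 * (p_rstar + a.vdw_rstar) for a in receptor.atoms])
    for chunk in range(0, points.shape[0], 4096):
        pts = points[chunk : chunk + 4096]
        r = np.linalg.norm(pts[:, None, :] - rx[None, :, :], axis=-1)
        r = np.maximum(r, 1e-6)
        out[chunk : chunk + 4096] = np.sum(
            _pair_vdw_arrays(eps[None, :], rstar[None, :], r), axis=1
        )
    return out


def direct_energy(
    receptor: Receptor,
    topology: LigandTopology,
    conformer: Conformer,
    solvent: SolventModel | None = None,
    include_np: bool = False,
    include_internal: bool = True,
) -> EnergyBreakdown:
    """Gridless evaluation of the docking energy model (exact pair sums).

    Uses exactly the same per-atom potentials that the field grids tabulate
    (Coulomb, buffered-14-7 vdW, quadratic-in-charge desolvation penalty),
    so a grid built with zero broadening reproduces this value at lattice
    nodes.  Nonpolar desolvation is excluded by default because the docking
    grids do not carry it.
    """
    solvent = solvent or SolventModel()
    x = conformer.coords
    q = topology.charges()
    e_c = float(
        np.sum(q * receptor_potential(receptor, x, "coulomb", solvent))
    )
    e_v = 0.0
    for k, atom in enumerate(topology.atoms):
        e_v += float(
            receptor_potential(
                receptor,
                x[k],
                atom.ff_type,
                solvent,
                probe_vdw=(atom.vdw_eps, atom.vdw_rstar),
            )[0]
        )
    e_p = float(
        np.sum(q**2 * born_desolvation_field(receptor, x, solvent=solvent))
    )
    e_n = (
        nonpolar_desolvation(receptor, topology, conformer, solvent)
        if include_np
        else 0.0
    )
    e_i = ligand_internal_energy(topology, conformer, solvent) if include_internal else 0.0
    return EnergyBreakdown(
        e_coulomb=e_c, e_vdw=e_v, e_pol=e_p, e_np=e_n, e_internal=e_i
    )
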