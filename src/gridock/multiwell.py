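"""Multiwell binding free energies from pools of local energy minima.

A ligand (free or in the receptor field) is not a single pose: at
equilibrium it populates many nearby local minima.  The multiwell
approximation treats each located minimum i as an independent harmonic
well with free energy

    Gⁱ = E₀ⁱ + G_vⁱ + G_tⁱ + G_rⁱ,

where E₀ⁱ is the potential energy at the minimum and the vibrational,
translational and rotational terms come from classical partition sums
(harmonic oscillator per normal mode, particle in an effective volume,
rigid rotor).  The total free energy is the Boltzmann-weighted sum over
the pool,

    G = −kT·ln Σᵢ exp(−Gⁱ/kT),

evaluated with a shifted log-sum-exp for numerical stability.  Minima are
found by Monte-Carlo perturbation (random torsion deformations and random
rigid rotations/translations) followed by local L-BFGS minimization; up
to 1024 distinct minima with the lowest potential energies are kept.

The minima search runs without solvent by default; a continuum-solvent
term may be added at final scoring.  Classical (not quantum) oscillator
sums are used — they are zero-point-energy-free and switchable via
``quantum=True`` in :func:`well_free_energy`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .chemio import Conformer, LigandTopology, Receptor
from .energetics import SolventModel, ligand_internal_energy

KB_KCAL = 1.9872041e-3  # kcal/(mol·K)
H_KCAL_S = 6.62607015e-34 * 6.02214076e23 / 4184.0  # Planck, kcal·s/mol
KB_SI = 1.380649e-23  # J/K
H_SI = 6.62607015e-34  # J·s
AMU = 1.66053906660e-27  # kg
# mass-weighted hessian eigenvalue (kcal/mol/Å²/amu) -> angular frequency² (s⁻²)
OMEGA2_CONV = 4184.0 / (6.02214076e23 * AMU * 1e-20)

STANDARD_VOLUME = 1660.0  # Å³ per molecule at 1 M
POOL_CAPACITY = 1024


@dataclass
class LocalMinimum:
    """One harmonic well: pose, potential energy, mode frequencies, free energy."""

    conformer: Conformer
    e0: float
    frequencies: np.ndarray = field(default_factory=lambda: np.array([]))
    g_v: float = 0.0
    g_t: float = 0.0
    g_r: float = 0.0

    @property
    def g_total(self) -> float:
        return self.e0 + self.g_v + self.g_t + self.g_r


@dataclass
class MinimaPool:
    """Sorted pool of distinct local minima (capacity 1024)."""

    minima: list[LocalMinimum] = field(default_factory=list)
    capacity: int = POOL_CAPACITY
    dedup_rmsd: float = 0.5  # Å
    dedup_de: float = 0.1  # kcal/mol
    temperature: float = 298.15  # K
    dedup_align: bool = False  # superpose before RMSD (free-ligand pools)

    def _rmsd(self, a: np.ndarray, b: np.ndarray) -> float:
        if self.dedup_align and a.shape[0] > 1:
            from scipy.spatial.transform import Rotation

            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            rot, _ = Rotation.align_vectors(ac, bc)
            b_aligned = rot.apply(bc)
            d = ac - b_aligned
        else:
            d = a - b
        return math.sqrt(float(np.mean(np.sum(d * d, axis=1))))

    def insert(self, candidate: LocalMinimum) -> bool:
        """Insert unless a member matches (RMSD < dedup_rmsd AND |ΔE₀| < dedup_de);
        evict the worst member at capacity.  Returns True if inserted.

        In the receptor frame the RMSD is raw (poses in different wells of
        the site must stay distinct); with ``dedup_align`` the conformers
        are superposed first, merging free-ligand minima that differ only
        by rigid motion.
        """
        for m in self.minima:
            if abs(m.e0 - candidate.e0) < self.dedup_de:
                if self._rmsd(m.conformer.coords, candidate.conformer.coords) < self.dedup_rmsd:
                    return False
        self.minima.append(candidate)
        self.minima.sort(key=lambda m: m.e0)
        if len(self.minima) > self.capacity:
            self.minima = self.minima[: self.capacity]
        return True

    @property
    def best(self) -> LocalMinimum:
        if not self.minima:
            raise ValueError("empty pool")
        return self.minima[0]


@dataclass
class FLMParams:
    """Monte-Carlo minima-search parameters."""

    n_starts: int = 100
    torsion_step: float = math.pi  # rad, uniform half-width
    translation_step: float = 0.5  # Å, Gaussian sigma
    rotation_step: float = 0.5  # rad, Gaussian sigma
    seed: int = 0
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if min(self.torsion_step, self.translation_step, self.rotation_step) <= 0:
            raise ValueError("perturbation steps must be positive")


# ---------------------------------------------------------------------------
# energy models (full force field, gridless)


class EnergyModel:
    """Callable potential over ligand Cartesian coordinates.

    ``energy(coords)`` takes an (n, 3) array in Å and returns kcal/mol;
    ``masses`` is the per-atom mass vector (amu).
    """

    masses: np.ndarray

    def energy(self, coords: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError

    def energy_flat(self, x: np.ndarray) -> float:
        return self.energy(x.reshape(-1, 3))


class _RestraintMixin:
    """Stiff harmonic restraints that realize rigid bond lengths/angles.

    The internal energy carries no bond or angle terms (those coordinates
    are frozen in the model), so Cartesian minimization needs restraints
    to the reference internal geometry; they vanish at the reference
    values and only torsions and rigid motions remain soft.
    """

    def _setup_restraints(
        self, topology: LigandTopology, reference: Conformer, k_bond: float, k_angle: float
    ) -> None:
        self._k_bond = k_bond
        self._k_angle = k_angle
        x = reference.coords
        self._bond_refs = [
            (b.i, b.j, float(np.linalg.norm(x[b.i] - x[b.j]))) for b in topology.bonds
        ]
        adj = topology.adjacency()
        self._angle_refs = []
        for j, nbrs in enumerate(adj):
            for a_i in range(len(nbrs)):
                for b_i in range(a_i + 1, len(nbrs)):
                    i, k = nbrs[a_i], nbrs[b_i]
                    self._angle_refs.append((i, j, k, _angle(x[i], x[j], x[k])))

    def _restraint_energy(self, x: np.ndarray) -> float:
        e = 0.0
        for i, j, d0 in self._bond_refs:
            d = float(np.linalg.norm(x[i] - x[j]))
            e += self._k_bond * (d - d0) ** 2
        for i, j, k, t0 in self._angle_refs:
            e += self._k_angle * (_angle(x[i], x[j], x[k]) - t0) ** 2
        return e


def _angle(a, b, c) -> float:
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.acos(max(-1.0, min(1.0, cosang)))


class FreeLigandModel(EnergyModel, _RestraintMixin):
    """Intramolecular energy of the free ligand (restrained rigid geometry)."""

    def __init__(
        self,
        topology: LigandTopology,
        reference: Conformer,
        solvent: SolventModel | None = None,
        k_bond: float = 300.0,
        k_angle: float = 60.0,
    ) -> None:
        self.topology = topology
        self.solvent = solvent or SolventModel()
        self.masses = np.array([a.mass for a in topology.atoms])
        self._setup_restraints(topology, reference, k_bond, k_angle)

    def energy(self, coords: np.ndarray) -> float:
        conf = Conformer(np.asarray(coords, dtype=float))
        return (
            ligand_internal_energy(self.topology, conf, self.solvent)
            + self._restraint_energy(conf.coords)
        )


class ComplexModel(EnergyModel, _RestraintMixin):
    """Full gridless protein–ligand potential (rigid receptor).

    Intermolecular Coulomb + buffered-14-7 vdW by exact pair sums plus the
    ligand's internal energy; solvent excluded by default (added at final
    scoring when requested).
    """

    def __init__(
        self,
        receptor: Receptor,
        topology: LigandTopology,
        reference: Conformer,
        solvent: SolventModel | None = None,
        k_bond: float = 300.0,
        k_angle: float = 60.0,
    ) -> None:
        self.receptor = receptor
        self.topology = topology
        self.solvent = solvent or SolventModel()
        self.masses = np.array([a.mass for a in topology.atoms])
        self._setup_restraints(topology, reference, k_bond, k_angle)
        self._rx = receptor.coords
        self._rq = receptor.charges()
        self._reps = np.array([a.vdw_eps for a in receptor.atoms])
        self._rrs = np.array([a.vdw_rstar for a in receptor.atoms])

    def intermolecular(self, coords: np.ndarray) -> float:
        x = np.asarray(coords, dtype=float)
        e = 0.0
        for k, atom in enumerate(self.topology.atoms):
            r = np.linalg.norm(self._rx - x[k], axis=1)
            r = np.maximum(r, 1e-6)
            e += float(
                np.sum(
                    332.0716
                    * atom.partial_charge
                    * self._rq
                    / (self.solvent.eps_in * (r + 0.05))
                )
            )
            eps = np.sqrt(atom.vdw_eps * self._reps)
            rstar = 0.5 * (atom.vdw_rstar + self._rrs)
            rs7 = rstar**7
            a = (1.07 * rstar / (r + 0.07 * rstar)) ** 7
            b = 1.12 * rs7 / (r**7 + 0.12 * rs7) - 2.0
            e += float(np.sum(np.minimum(eps * a * b, 1e4)))
        return e

    def energy(self, coords: np.ndarray) -> float:
        conf = Conformer(np.asarray(coords, dtype=float))
        return (
            self.intermolecular(conf.coords)
            + ligand_internal_energy(self.topology, conf, self.solvent)
            + self._restraint_energy(conf.coords)
        )


# ---------------------------------------------------------------------------
# minima search


def local_minimize(
    energy_model: EnergyModel, start: Conformer, gtol: float = 1e-5, maxiter: int = 2000
) -> tuple[Conformer, float]:
    """L-BFGS local minimization over Cartesian coordinates."""
    x0 = start.coords.ravel()
    e0 = energy_model.energy_flat(x0)
    if not math.isfinite(e0):
        raise ValueError("non-finite starting energy")
    res = minimize(
        energy_model.energy_flat,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    e_final = float(res.fun)
    if e_final > e0 + 1e-9:  # descent contract: never return uphill
        return start.copy(), e0
    return Conformer(res.x.reshape(-1, 3)), e_final


def mc_minima_search(
    energy_model: EnergyModel,
    topology: LigandTopology,
    start: Conformer,
    params: FLMParams | None = None,
    pool: MinimaPool | None = None,
) -> MinimaPool:
    """Monte-Carlo local-minima search: perturb, minimize, pool.

    Each cycle applies random torsion deformations and a random rigid
    rotation/translation to the start pose, minimizes locally, and inserts
    the converged conformer into the pool under the (RMSD, ΔE₀) dedup
    rule.  Deterministic per seed.
    """
    from scipy.spatial.transform import Rotation

    params = params or FLMParams()
    rng = np.random.default_rng(params.seed)
    pool = pool or MinimaPool(temperature=params.temperature)
    conf, e = local_minimize(energy_model, start)
    pool.insert(LocalMinimum(conformer=conf, e0=e))
    for _ in range(params.n_starts):
        x = start.coords.copy()
        if topology.n_tors:
            from .gadock import apply_torsions

            angles = rng.uniform(
                -params.torsion_step, params.torsion_step, size=topology.n_tors
            )
            x = apply_torsions(topology, Conformer(x), angles).coords
        centroid = x.mean(axis=0)
        rot = Rotation.from_rotvec(rng.normal(0.0, params.rotation_step, size=3))
        shift = rng.normal(0.0, params.translation_step, size=3)
        x = rot.apply(x - centroid) + centroid + shift
        try:
            conf, e = local_minimize(energy_model, Conformer(x))
        except ValueError:
            continue
        pool.insert(LocalMinimum(conformer=conf, e0=e))
    return pool


# ---------------------------------------------------------------------------
# harmonic thermodynamics


def numerical_hessian(
    energy_model: EnergyModel, conformer: Conformer, step: float = 1e-3
) -> np.ndarray:
    """Central-finite-difference Cartesian hessian (kcal/mol/Å²)."""
    x0 = conformer.coords.ravel()
    n = x0.size
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += step; xpp[j] += step
            xpm = x0.copy(); xpm[i] += step; xpm[j] -= step
            xmp = x0.copy(); xmp[i] -= step; xmp[j] += step
            xmm = x0.copy(); xmm[i] -= step; xmm[j] -= step
            val = (
                energy_model.energy_flat(xpp)
                - energy_model.energy_flat(xpm)
                - energy_model.energy_flat(xmp)
                + energy_model.energy_flat(xmm)
            ) / (4.0 * step * step)
            hess[i, j] = hess[j, i] = val
    return hess


def _rigid_mode_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n = coords.shape[0]
    sq = np.sqrt(masses)
    com = np.average(coords, axis=0, weights=masses)
    rel = coords - com
    vecs = []
    for d in range(3):
        v = np.zeros((n, 3))
        v[:, d] = sq
        vecs.append(v.ravel())
    for d in range(3):
        e = np.zeros(3)
        e[d] = 1.0
        v = np.cross(rel, e) * sq[:, None]
        vecs.append(v.ravel())
    basis = []
    for v in vecs:
        for b in basis:
            v = v - np.dot(v, b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.array(basis).T if basis else np.zeros((3 * n, 0))


def harmonic_frequencies(
    energy_model: EnergyModel,
    topology: LigandTopology,
    conformer: Conformer,
    step: float = 1e-3,
    zero_tol: float = 1e-4,
    project_rigid: bool = True,
) -> np.ndarray:
    """Normal-mode frequencies (s⁻¹) of a converged minimum.

    Mass-weights the finite-difference hessian, projects out the six (five
    for linear, three for a point) rigid-body modes, and converts the
    remaining positive eigenvalues.  An eigenvalue significantly below
    zero means the input is not a minimum and raises.

    Projection matches the well free-energy decomposition, where rigid
    translations/rotations are carried by the separate translational and
    rotational partition sums; pass ``project_rigid=False`` to treat every
    Cartesian mode as vibrational (e.g. a particle bound in an external
    well).
    """
    masses = energy_model.masses
    hess = numerical_hessian(energy_model, conformer, step)
    sq = np.repeat(np.sqrt(masses), 3)
    hmw = hess / np.outer(sq, sq)
    basis = (
        _rigid_mode_basis(conformer.coords, masses)
        if project_rigid
        else np.zeros((hmw.shape[0], 0))
    )
    if basis.size:
        proj = np.eye(hmw.shape[0]) - basis @ basis.T
        hmw = proj @ hmw @ proj
    evals = np.linalg.eigvalsh(hmw)
    scale = max(1.0, float(np.max(np.abs(evals))))
    kept = evals[np.abs(evals) > zero_tol * scale]
    if np.any(kept < 0):
        raise ValueError("not a minimum: imaginary mode present")
    omega = np.sqrt(kept * OMEGA2_CONV)
    return omega / (2.0 * math.pi)


def moments_of_inertia(conformer: Conformer, masses: np.ndarray) -> np.ndarray:
    """Principal moments (amu·Å²), ascending."""
    com = np.average(conformer.coords, axis=0, weights=masses)
    rel = conformer.coords - com
    r2 = np.sum(rel * rel, axis=1)
    tensor = np.zeros((3, 3))
    for d in range(3):
        for e in range(3):
            tensor[d, e] = np.sum(
                masses * ((r2 if d == e else 0.0) - rel[:, d] * rel[:, e])
            )
    return np.sort(np.linalg.eigvalsh(tensor))


def vibrational_free_energy(
    frequencies: np.ndarray, temperature: float, quantum: bool = False
) -> float:
    """G_v from per-mode partition sums (classical by default).

    Classical: Z_v = Π kT/(hν) so G_v = Σ kT·ln(hν/kT); a mode with
    hν = kT contributes zero.
    """
    nu = np.asarray(frequencies, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("frequencies must be positive")
    kt = KB_KCAL * temperature
    hnu = H_KCAL_S * nu
    if quantum:
        return float(np.sum(hnu / 2.0 + kt * np.log(1.0 - np.exp(-hnu / kt))))
    return float(np.sum(kt * np.log(hnu / kt)))


def translational_free_energy(
    mass: float, temperature: float, volume: float = STANDARD_VOLUME
) -> float:
    """G_t of a particle in a volume (Å³): −kT·ln(V/Λ³)."""
    lam = H_SI / math.sqrt(2.0 * math.pi * mass * AMU * KB_SI * temperature)  # m
    z_t = volume * 1e-30 / lam**3
    return -KB_KCAL * temperature * math.log(z_t)


def rotational_free_energy(inertia: np.ndarray, temperature: float) -> float:
    """G_r of a classical rigid rotor; 0 for a point mass, linear-rotor
    form when one principal moment vanishes."""
    inertia = np.sort(np.asarray(inertia, dtype=float))
    inertia_si = inertia * AMU * 1e-20  # kg·m²
    kt_si = KB_SI * temperature
    tiny = 1e-3 * AMU * 1e-20
    if inertia_si[-1] < tiny:  # point mass
        return 0.0
    if inertia_si[0] < tiny:  # linear
        z_r = 8.0 * math.pi**2 * inertia_si[-1] * kt_si / H_SI**2
    else:
        z_r = (
            math.sqrt(math.pi)
            * (8.0 * math.pi**2 * kt_si / H_SI**2) ** 1.5
            * math.sqrt(float(np.prod(inertia_si)))
        )
    return -KB_KCAL * temperature * math.log(z_r)


def rigid_body_free_energy(
    mass: float, inertia: np.ndarray, temperature: float, volume: float
) -> float:
    """G_t + G_r of the whole ligand treated as a rigid body."""
    return translational_free_energy(mass, temperature, volume) + rotational_free_energy(
        inertia, temperature
    )


def well_free_energy(
    minimum: LocalMinimum,
    mass: float,
    inertia: np.ndarray,
    temperature: float,
    volume: float = STANDARD_VOLUME,
    quantum: bool = False,
) -> LocalMinimum:
    """Fill in a well's G_v, G_t, G_r so that g_total = E₀ + G_v + G_t + G_r."""
    minimum.g_v = (
        vibrational_free_energy(minimum.frequencies, temperature, quantum)
        if minimum.frequencies.size
        else 0.0
    )
    minimum.g_t = translational_free_energy(mass, temperature, volume)
    minimum.g_r = rotational_free_energy(inertia, temperature)
    return minimum


# ---------------------------------------------------------------------------
# multiwell aggregation


def multiwell_free_energy(pool: MinimaPool) -> float:
    """G = −kT·ln Σᵢ exp(−Gⁱ/kT) over the pool (stabilized log-sum-exp)."""
    if not pool.minima:
        raise ValueError("empty minima pool")
    kt = KB_KCAL * pool.temperature
    g = np.array([m.g_total for m in pool.minima])
    gmin = float(np.min(g))
    return gmin - kt * float(np.log(np.sum(np.exp(-(g - gmin) / kt))))


def well_populations(pool: MinimaPool) -> np.ndarray:
    """Equilibrium occupancies exp(−(Gⁱ−G)/kT); they sum to 1."""
    kt = KB_KCAL * pool.temperature
    g = np.array([m.g_total for m in pool.minima])
    w = np.exp(-(g - np.min(g)) / kt)
    return w / w.sum()


def strain_energy(
    bound: Conformer,
    free_pool: MinimaPool,
    topology: LigandTopology,
    solvent: SolventModel | None = None,
) -> float:
    """Ligand strain: internal energy of the bound pose minus the free
    ligand's global-minimum energy, clipped at zero."""
    if not free_pool.minima:
        raise ValueError("empty free-ligand pool")
    e_bound = ligand_internal_energy(topology, bound, solvent)
    e_free = free_pool.best.e0
    strain = e_bound - e_free
    if strain < 0:
        warnings.warn(
            "negative strain energy clipped to 0; free-ligand search may be "
            "unconverged"
        )
        return 0.0
    return strain


def binding_free_energy(
    complex_pool: MinimaPool,
    free_ligand_pool: MinimaPool,
    g_protein_reference: float = 0.0,
) -> float:
    """ΔG_bind = G(complex) − G(free ligand) − G(protein reference).

    The protein reference is a constant that cancels when comparing
    ligands; it defaults to zero.
    """
    if abs(complex_pool.temperature - free_ligand_pool.temperature) > 1e-9:
        raise ValueError("pool temperatures differ")
    return (
        multiwell_free_energy(complex_pool)
        - multiwell_free_energy(free_ligand_pool)
        - g_protein_reference
    )
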