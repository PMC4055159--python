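"""Genetic-algorithm docking over grid-interpolated receptor potentials.

The pose is encoded as a genome of 7 + N_TORS real genes: a translation,
a unit quaternion, and one delta angle per rotatable torsion applied to
the reference conformer.  Bond lengths and angles never change; there is
no local optimization during the search — the GA alone must find the
global minimum of the grid energy inside the docking cube.

The score is a weighted sum of the grid energy components plus a
torsional-entropy penalty of 0.33 kcal/mol per rotatable bond.  Poses
whose score falls below −5.5 kcal/mol are classified as predicted
inhibitors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .chemio import Conformer, LigandTopology
from .energetics import EnergyBreakdown
from .fieldgrid import GridSet, grid_energy, interpolate

ENTROPY_PER_TORSION = 0.33  # kcal/mol per rotatable torsion
SCORE_THRESHOLD = -5.5  # kcal/mol; below => predicted inhibitor


@dataclass
class PoseGenome:
    """Translation (Å), orientation (unit quaternion, xyzw), torsion deltas."""

    translation: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        norm = np.linalg.norm(self.orientation)
        if norm == 0:
            raise ValueError("orientation quaternion must be nonzero")
        self.orientation = self.orientation / norm
        self.torsions = wrap_angles(self.torsions)

    @classmethod
    def identity(cls, n_tors: int) -> "PoseGenome":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(n_tors))

    def vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.orientation, self.torsions])


def wrap_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    a = np.asarray(angles, dtype=float)
    return -((-a + math.pi) % (2.0 * math.pi) - math.pi)


@dataclass
class GAParams:
    """Genetic-algorithm hyperparameters (all exposed; defaults desk-scale)."""

    population: int = 300
    generations: int = 100
    mutation_rate: float = 0.25
    crossover_rate: float = 0.8
    elite_fraction: float = 0.05
    n_runs: int = 10
    seed: int = 0
    tournament_size: int = 3
    translation_sigma: float = 0.75  # Å
    rotation_sigma: float = 0.35  # rad
    torsion_sigma: float = 0.6  # rad

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for rate in (self.mutation_rate, self.crossover_rate, self.elite_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SolScore:
    """Component-wise docking score, kcal/mol."""

    e_coulomb: float
    e_vdw: float
    e_pol: float
    entropy_term: float
    total: float


def sol_score(
    breakdown: EnergyBreakdown,
    n_tors: int,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SolScore:
    """Weighted component sum plus the 0.33·N_TORS entropy penalty.

    The component weights of the original scoring function are treated as
    configuration (unit weights by default).
    """
    entropy = ENTROPY_PER_TORSION * n_tors
    total = (
        weights[0] * breakdown.e_coulomb
        + weights[1] * breakdown.e_vdw
        + weights[2] * breakdown.e_pol
        + entropy
    )
    return SolScore(
        e_coulomb=breakdown.e_coulomb,
        e_vdw=breakdown.e_vdw,
        e_pol=breakdown.e_pol,
        entropy_term=entropy,
        total=total,
    )


def classify_predicted(score_total: float) -> str:
    """'inhibitor' iff the score is strictly below −5.5 kcal/mol."""
    if not math.isfinite(score_total):
        raise ValueError("score must be finite")
    return "inhibitor" if score_total < SCORE_THRESHOLD else "non-inhibitor"


# ---------------------------------------------------------------------------
# genome application


def apply_torsions(
    topology: LigandTopology, conformer: Conformer, angles: np.ndarray
) -> Conformer:
    """Rotate each torsion's moving set about its axis bond by a delta angle."""
    angles = np.asarray(angles, dtype=float)
    if angles.shape[0] != topology.n_tors:
        raise ValueError("torsion angle count mismatch")
    x = conformer.coords.copy()
    for t, ang in zip(topology.rotatable_torsions, angles):
        if ang == 0.0:
            continue
        axis = x[t.b] - x[t.a]
        axis = axis / np.linalg.norm(axis)
        # sign: positive delta increments the signed dihedral by +delta
        rot = Rotation.from_rotvec(-ang * axis)
        idx = sorted(t.moving)
        x[idx] = rot.apply(x[idx] - x[t.b]) + x[t.b]
    return Conformer(x)


def apply_genome(
    topology: LigandTopology, reference: Conformer, genome: PoseGenome
) -> Conformer:
    """Torsions, then rigid rotation about the centroid, then translation.

    The identity genome reproduces the reference coordinates; bond lengths
    and angles are preserved exactly (rigid internal geometry).
    """
    if genome.torsions.shape[0] != topology.n_tors:
        raise ValueError("genome torsion count != topology n_tors")
    conf = apply_torsions(topology, reference, genome.torsions)
    centroid = conf.coords.mean(axis=0)
    rot = Rotation.from_quat(genome.orientation)
    coords = rot.apply(conf.coords - centroid) + centroid + genome.translation
    return Conformer(coords)


# ---------------------------------------------------------------------------
# GA search


def _score_genome(
    grids: GridSet,
    topology: LigandTopology,
    reference: Conformer,
    genome: PoseGenome,
    weights: tuple[float, float, float],
) -> tuple[SolScore, Conformer]:
    conf = apply_genome(topology, reference, genome)
    return sol_score(grid_energy(grids, topology, conf), topology.n_tors, weights), conf


def _random_genome(
    rng: np.random.Generator,
    grids: GridSet,
    reference: Conformer,
    n_tors: int,
) -> PoseGenome:
    cube = grids.cube
    half = cube.edge / 2.0
    target = cube.center + rng.uniform(-half, half, size=3)
    translation = target - reference.coords.mean(axis=0)
    quat = rng.normal(size=4)
    torsions = rng.uniform(-math.pi, math.pi, size=n_tors)
    return PoseGenome(translation, quat, torsions)


def _mutate(
    genome: PoseGenome, rng: np.random.Generator, params: GAParams
) -> PoseGenome:
    t = genome.translation.copy()
    q = genome.orientation.copy()
    tor = genome.torsions.copy()
    # two-scale mutation: coarse kicks explore, fine kicks converge
    scale = 1.0 if rng.random() < 0.5 else 0.05
    if rng.random() < params.mutation_rate:
        t = t + rng.normal(0.0, scale * params.translation_sigma, size=3)
    if rng.random() < params.mutation_rate:
        kick = Rotation.from_rotvec(
            rng.normal(0.0, scale * params.rotation_sigma, size=3)
        )
        q = (kick * Rotation.from_quat(q)).as_quat()
    for k in range(tor.shape[0]):
        if rng.random() < params.mutation_rate:
            tor[k] += rng.normal(0.0, scale * params.torsion_sigma)
    return PoseGenome(t, q, tor)


def _crossover(
    a: PoseGenome, b: PoseGenome, rng: np.random.Generator
) -> PoseGenome:
    t = np.where(rng.random(3) < 0.5, a.translation, b.translation)
    q = a.orientation if rng.random() < 0.5 else b.orientation
    tor = np.where(
        rng.random(a.torsions.shape[0]) < 0.5, a.torsions, b.torsions
    ) if a.torsions.size else a.torsions
    return PoseGenome(t, q.copy(), tor)


def ga_search(
    grids: GridSet,
    topology: LigandTopology,
    reference: Conformer,
    params: GAParams | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    dedup_rmsd: float = 1.0,
    keep: int = 20,
) -> list[tuple[PoseGenome, SolScore]]:
    """Dock by pooled independent GA runs; returns ranked, deduplicated poses.

    Tournament selection, uniform crossover, Gaussian mutation, elitism.
    Deterministic for a given seed.  Poses closer than ``dedup_rmsd``
    (all-atom RMSD) keep only the lower-scoring member; output is sorted
    ascending by total score with (e_vdw, genome lexicographic) tie-breaks.
    """
    params = params or GAParams()
    if grids.cube is None:
        raise ValueError("empty grid set")
    grids.ensure_vdw(topology)
    n_tors = topology.n_tors
    elite_n = max(1, int(round(params.elite_fraction * params.population)))
    pool: list[tuple[PoseGenome, SolScore, Conformer]] = []
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_runs)
    for run_seed in seeds:
        rng = np.random.default_rng(run_seed)
        population = [
            _random_genome(rng, grids, reference, n_tors)
            for _ in range(params.population)
        ]
        scored = [
            (g, *_score_genome(grids, topology, reference, g, weights))
            for g in population
        ]
        scored.sort(key=lambda gs: gs[1].total)
        for _ in range(params.generations):
            nxt = scored[:elite_n]
            while len(nxt) < params.population:
                parents = []
                for _k in range(2):
                    contenders = rng.integers(0, params.population, params.tournament_size)
                    parents.append(min(contenders, key=lambda i: scored[i][1].total))
                child = (
                    _crossover(scored[parents[0]][0], scored[parents[1]][0], rng)
                    if rng.random() < params.crossover_rate
                    else scored[parents[0]][0]
                )
                child = _mutate(child, rng, params)
                nxt.append((child, *_score_genome(grids, topology, reference, child, weights)))
            scored = sorted(nxt, key=lambda gs: gs[1].total)[: params.population]
        pool.extend(scored[: max(keep, elite_n)])
    # dedup: all-atom RMSD < dedup_rmsd keeps the lower-scoring pose
    pool.sort(key=lambda gs: (gs[1].total, gs[1].e_vdw, tuple(gs[0].vector())))
    kept: list[tuple[PoseGenome, SolScore, Conformer]] = []
    for cand in pool:
        dup = False
        for ref in kept:
            rmsd = float(
                np.sqrt(np.mean(np.sum((cand[2].coords - ref[2].coords) ** 2, axis=1)))
            )
            if rmsd < dedup_rmsd:
                dup = True
                break
        if not dup:
            kept.append(cand)
    return [(g, s) for g, s, _c in kept]


def lattice_scan_argmin(
    grids: GridSet, topology: LigandTopology
) -> tuple[np.ndarray, float]:
    """Exhaustive node scan for a single-atom ligand: brute-force reference.

    Evaluates q·C + q²·D + V_type at every lattice node and returns the
    best node position and its energy.  Only defined for one-atom ligands
    (for which orientation and torsions are irrelevant).
    """
    if topology.n_atoms != 1:
        raise ValueError("lattice scan reference is defined for 1-atom ligands")
    grids.ensure_vdw(topology)
    a = topology.atoms[0]
    field = (
        a.partial_charge * grids.coulomb
        + a.partial_charge**2 * grids.desolv
        + grids.vdw[a.ff_type]
    )
    flat = int(np.argmin(field))
    n = grids.cube.n_nodes
    idx = np.unravel_index(flat, (n, n, n))
    point = grids.cube.origin + grids.cube.spacing * np.array(idx, dtype=float)
    return point, float(field[idx])
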