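"""Post-docking rescoring: local optimization, seven-component empirical
scoring, and coefficient fitting against experimental affinities.

The docked pose is relaxed in the full (gridless) force field and its
binding free energy estimated as the linear combination

    ΔG_bind = k₁ΔG_Coulomb + k₂ΔG_VdW + k₃ΔG_pol + k₄ΔG_np
            + k₅ΔG_LS + k₆·0.33·N_TORS + k₇ΔG_rot-tr,

with components in kcal/mol: direct Coulomb and van der Waals interaction
energies, polar (generalized-Born) and nonpolar (buried-surface) parts of
the desolvation energy, the ligand strain energy ΔG_LS, a torsional
entropy term 0.33 kcal/mol per rotatable bond, and the rigid-body
rotational/translational free-energy loss ΔG_rot-tr.  The unitless
coefficients k₁..k₇ are fitted by ordinary least squares to experimental
binding free energies ΔG = RT·ln(Ki) — the closed-form optimum of the
iterative mean-square fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemio import (
    GAS_CONSTANT_KCAL,
    AtomRecord,
    Conformer,
    LigandTopology,
    Receptor,
)
from .energetics import (
    EnergyBreakdown,
    SolventModel,
    gb_polar_desolvation,
    ligand_internal_energy,
    nonpolar_desolvation,
)
from .gadock import ENTROPY_PER_TORSION
from .multiwell import (
    STANDARD_VOLUME,
    ComplexModel,
    MinimaPool,
    local_minimize,
    moments_of_inertia,
    rigid_body_free_energy,
)

KI_THRESHOLD = 1e-5  # molar (10 µM); below => experimental inhibitor

# Published urokinase-trained coefficient sets for the seven-component
# score (unitless), fitted on 50 and on 88 protein-ligand complexes.
UPA_COEFFS_TRAIN50 = (0.0292, 0.1295, 0.2437, -0.0438, 0.4958, 0.2597, 0.0393)
UPA_COEFFS_ALL88 = (0.0387, 0.1387, 0.1162, -0.0188, 0.1081, 0.0504, 0.0322)

_COLUMN_NAMES = (
    "dg_coulomb",
    "dg_vdw",
    "dg_pol",
    "dg_np",
    "dg_ls",
    "torsion_entropy",
    "dg_rot_tr",
)


@dataclass
class DiscoreComponents:
    """Per-complex energy components entering the seven-term score."""

    dg_coulomb: float
    dg_vdw: float
    dg_pol: float
    dg_np: float
    dg_ls: float
    n_tors: int
    dg_rot_tr: float

    def __post_init__(self) -> None:
        if self.dg_ls < 0:
            raise ValueError("strain energy is a penalty: dg_ls >= 0")
        if self.n_tors < 0:
            raise ValueError("n_tors >= 0")

    def design_row(self) -> np.ndarray:
        """The 7-column regression row; the torsion column is 0.33·N_TORS."""
        return np.array(
            [
                self.dg_coulomb,
                self.dg_vdw,
                self.dg_pol,
                self.dg_np,
                self.dg_ls,
                ENTROPY_PER_TORSION * self.n_tors,
                self.dg_rot_tr,
            ]
        )


@dataclass
class CoefficientVector:
    """The seven unitless adjustment coefficients k₁..k₇."""

    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if self.k.shape != (7,) or not np.all(np.isfinite(self.k)):
            raise ValueError("coefficient vector must be 7 finite values")

    def __iter__(self):
        return iter(self.k)


def discore_score(
    components: DiscoreComponents, k: CoefficientVector | tuple
) -> float:
    """Evaluate the seven-term empirical binding free energy, kcal/mol."""
    kv = k.k if isinstance(k, CoefficientVector) else np.asarray(k, dtype=float)
    return float(np.dot(kv, components.design_row()))


def fit_coefficients(
    component_rows: list[DiscoreComponents], dg_exp
) -> CoefficientVector:
    """Ordinary least squares for k₁..k₇ (closed-form mean-square optimum).

    Raises when there are fewer rows than coefficients or when the design
    matrix is rank deficient (the offending column is named).
    """
    if len(component_rows) < 7:
        raise ValueError("need at least 7 component rows to fit 7 coefficients")
    design = np.array([c.design_row() for c in component_rows])
    y = np.asarray(dg_exp, dtype=float)
    if y.shape[0] != design.shape[0]:
        raise ValueError("row/response length mismatch")
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        for col in range(7):
            others = np.delete(design, col, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(
                    f"design matrix rank deficient: column {_COLUMN_NAMES[col]!r} "
                    "is degenerate"
                )
        raise ValueError("design matrix rank deficient")
    k, *_ = np.linalg.lstsq(design, y, rcond=None)
    return CoefficientVector(k)


# ---------------------------------------------------------------------------
# activity conversion and classification


def ki_to_dg(ki: float, temperature: float = 298.15) -> float:
    """ΔG = RT·ln(Ki), kcal/mol, with R = 1.9872e-3 kcal/(mol·K)."""
    if ki <= 0:
        raise ValueError("Ki must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(ki)


def classify_experimental(ki: float) -> str:
    """'inhibitor' iff Ki < 10 µM (strict)."""
    if ki <= 0:
        raise ValueError("Ki must be positive")
    return "inhibitor" if ki < KI_THRESHOLD else "non-inhibitor"


def confusion_counts(predicted, experimental) -> tuple[int, int]:
    """(FP, FN): FP = experimental non-inhibitor predicted as inhibitor;
    FN = experimental inhibitor predicted as non-inhibitor."""
    predicted = list(predicted)
    experimental = list(experimental)
    if len(predicted) != len(experimental):
        raise ValueError("label vectors differ in length")
    fp = sum(
        1
        for p, e in zip(predicted, experimental)
        if p == "inhibitor" and e == "non-inhibitor"
    )
    fn = sum(
        1
        for p, e in zip(predicted, experimental)
        if p == "non-inhibitor" and e == "inhibitor"
    )
    return fp, fn


# ---------------------------------------------------------------------------
# local optimization and component extraction


def local_optimize(
    receptor: Receptor,
    topology: LigandTopology,
    start: Conformer,
    solvent: SolventModel | None = None,
    gtol: float = 0.05,
    maxiter: int = 2000,
) -> tuple[Conformer, EnergyBreakdown]:
    """Relax the docked pose by quasi-Newton Cartesian minimization.

    The receptor stays fixed; ligand bond lengths and angles are held by
    stiff restraints while torsions and rigid motions relax.  Final energy
    never exceeds the starting energy.  Returns the relaxed conformer and
    its full-force-field component breakdown (with solvent terms).
    """
    solvent = solvent or SolventModel()
    model = ComplexModel(receptor, topology, start, solvent)
    conf, _e = local_minimize(model, start, gtol=gtol, maxiter=maxiter)
    breakdown = full_breakdown(receptor, topology, conf, solvent)
    return conf, breakdown


def full_breakdown(
    receptor: Receptor,
    topology: LigandTopology,
    conformer: Conformer,
    solvent: SolventModel | None = None,
) -> EnergyBreakdown:
    """Full-force-field components at a pose, with GB/SA solvent terms.

    Polar desolvation is ΔG_pol(complex) − ΔG_pol(protein) − ΔG_pol(ligand),
    each in the same GB model.
    """
    solvent = solvent or SolventModel()
    model = ComplexModel(receptor, topology, conformer, solvent)
    x = conformer.coords
    # split intermolecular into Coulomb / vdW parts via the pair sums
    e_c = 0.0
    e_v = 0.0
    rx = receptor.coords
    rq = receptor.charges()
    reps = np.array([a.vdw_eps for a in receptor.atoms])
    rrs = np.array([a.vdw_rstar for a in receptor.atoms])
    for kk, atom in enumerate(topology.atoms):
        r = np.maximum(np.linalg.norm(rx - x[kk], axis=1), 1e-6)
        e_c += float(
            np.sum(332.0716 * atom.partial_charge * rq / (solvent.eps_in * (r + 0.05)))
        )
        eps = np.sqrt(atom.vdw_eps * reps)
        rstar = 0.5 * (atom.vdw_rstar + rrs)
        rs7 = rstar**7
        e_v += float(
            np.sum(
                eps
                * (1.07 * rstar / (r + 0.07 * rstar)) ** 7
                * (1.12 * rs7 / (r**7 + 0.12 * rs7) - 2.0)
            )
        )
    lig_atoms = [
        AtomRecord(
            element=a.element,
            position=x[kk],
            partial_charge=a.partial_charge,
            ff_type=a.ff_type,
            vdw_eps=a.vdw_eps,
            vdw_rstar=a.vdw_rstar,
            born_radius=a.born_radius,
        )
        for kk, a in enumerate(topology.atoms)
    ]
    e_pol = (
        gb_polar_desolvation(receptor.atoms + lig_atoms, solvent)
        - gb_polar_desolvation(receptor.atoms, solvent)
        - gb_polar_desolvation(lig_atoms, solvent)
    )
    e_np = nonpolar_desolvation(receptor, topology, conformer, solvent)
    e_int = ligand_internal_energy(topology, conformer, solvent)
    return EnergyBreakdown(
        e_coulomb=e_c, e_vdw=e_v, e_pol=e_pol, e_np=e_np, e_internal=e_int
    )


def compute_components(
    receptor: Receptor,
    topology: LigandTopology,
    conformer: Conformer,
    solvent: SolventModel | None = None,
    free_pool: MinimaPool | None = None,
    temperature: float = 298.15,
    bound_volume: float = 1.0,
) -> DiscoreComponents:
    """Assemble the seven score components at an (optimized) pose.

    ``free_pool`` supplies the free-ligand global minimum for the strain
    term; without it the strain is referenced to the pose itself (zero).
    ΔG_rot-tr is the rigid-body free-energy change from the 1 M standard
    volume to an effective bound volume (default 1 Å³).
    """
    solvent = solvent or SolventModel()
    breakdown = full_breakdown(receptor, topology, conformer, solvent)
    if free_pool is not None and free_pool.minima:
        from .multiwell import strain_energy

        dg_ls = strain_energy(conformer, free_pool, topology, solvent)
    else:
        dg_ls = 0.0
    masses = np.array([a.mass for a in topology.atoms])
    inertia = moments_of_inertia(conformer, masses)
    dg_rot_tr = rigid_body_free_energy(
        float(masses.sum()), inertia, temperature, bound_volume
    ) - rigid_body_free_energy(
        float(masses.sum()), inertia, temperature, STANDARD_VOLUME
    )
    return DiscoreComponents(
        dg_coulomb=breakdown.e_coulomb,
        dg_vdw=breakdown.e_vdw,
        dg_pol=breakdown.e_pol,
        dg_np=breakdown.e_np,
        dg_ls=dg_ls,
        n_tors=topology.n_tors,
        dg_rot_tr=dg_rot_tr,
    )
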