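# gridock

Grid-based genetic-algorithm docking, empirical rescoring, and multiwell
binding free energies for protein–ligand systems.

Structure-based inhibitor discovery against enzymes such as urokinase-type
plasminogen activator (uPA) — whose trypsin-like S1 pocket anchors cationic
ligand groups at a buried aspartate — needs three tiers of modelling, from
fast to careful.  `gridock` implements all three at desk scale, plus the
statistics used to validate them:

1. **Docking.**  The receptor is rigid; its Coulomb, van der Waals
   (MMFF94-style buffered forms) and generalized-Born desolvation
   potentials are precomputed on a uniform lattice over a docking cube
   (default 22 Å edge).  A *broadening* of the atomic potentials — each
   node stores the minimum of the potential over a 7-point stencil of
   radius b ≈ 0.3–0.4 Å — partially accounts for receptor-atom mobility.
   A genetic algorithm searches ligand translation, orientation, and
   torsions (bond lengths and angles fixed, no local optimization) for the
   global energy minimum.  The docking score adds an entropy penalty of
   0.33 kcal/mol per rotatable torsion; scores below −5.5 kcal/mol flag
   predicted inhibitors, and Ki < 10 µM (ΔG = RT·ln Ki) flags experimental
   ones.

2. **Rescoring.**  The docked pose is relaxed by L-BFGS in the full
   force field with GB/SA solvent and scored with the seven-component
   empirical free energy

   ΔG_bind = k₁ΔG_Coulomb + k₂ΔG_VdW + k₃ΔG_pol + k₄ΔG_np + k₅ΔG_LS
           + k₆·0.33·N_TORS + k₇ΔG_rot-tr ,

   whose unitless coefficients k₁…k₇ are fitted to experimental binding
   free energies by least squares (`fit_coefficients`); two published
   urokinase-trained coefficient sets ship as references.

3. **Multiwell free energies.**  Monte-Carlo perturbation + local
   minimization builds a pool of up to 1024 distinct local minima of the
   complex and of the free ligand.  Each minimum i is a harmonic well with
   Gⁱ = E₀ⁱ + G_vⁱ + G_tⁱ + G_rⁱ, and the pool combines by
   G = −kT·ln Σᵢ exp(−Gⁱ/kT).  The difference of complex and free-ligand
   pools gives the binding free energy, including ligand strain.

4. **Evaluation.**  Pose RMSD with the excellent/good/satisfactory/bad
   grading at 1/2/3 Å, enrichment plots with area S_E, Mann–Whitney ROC
   AUC, Pearson correlation, and redocking/crossdocking/virtual-screen
   pipelines.

Every stage is testable offline: `make_toy_pocket` builds a synthetic S1-like
cavity (apolar shell + charged anchor) and `make_toy_ligand` a chain ligand
with any number of rotatable torsions.

## Worked example

```python
import numpy as np
import gridock as g
from gridock.fieldgrid import DockingCube, GridSet
from gridock.gadock import GAParams, ga_search

pocket = g.make_toy_pocket(seed=0)                    # charged anchor at -6 Å
topo, conf = g.make_toy_ligand(n_torsions=1, seed=0)  # cationic chain ligand
cube = DockingCube(center=np.array([0., 0., -1.]), edge=10.0, spacing=0.5)
grids = GridSet.build(pocket, cube, broadening=0.0)
ranked = ga_search(grids, topo, conf, GAParams(population=60, generations=60,
                                               n_runs=3, seed=1))
genome, score = ranked[0]
print(round(score.total, 3), round(score.e_coulomb, 3), score.entropy_term)
```

prints

```
-33.648 -152.465 0.33
```

— the best pose's docking score (kcal/mol), its Coulomb component (the
charged head pairing with the anchor), and the one-torsion entropy
penalty.  `examples/` contains four narrative scripts, one per capability
(docking, rescoring + coefficient fitting, multiwell free energies,
screening statistics); each prints its numbers with a short explanation.

A thin CLI mirrors the library for shell use:

```bash
gridock fixtures --ligand-torsions 1 --seed 0 --out fx
gridock grid --receptor fx/pocket.pdb --center 0,0,-1 --edge 8 --out grids
gridock dock --grids grids --ligand fx/ligand.sdf --seed 1 --out poses.sdf
gridock eval --scores scored_library.csv
```

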