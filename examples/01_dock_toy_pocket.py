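"""Dock a small charged ligand into the synthetic pocket.

Builds the toy receptor (an apolar hemispherical shell with a charged
anchor at its base), precomputes the potential grids over a docking cube,
and runs the genetic-algorithm pose search.  Prints the top poses with
their score components.
"""

import numpy as np

import gridock as g
from gridock.fieldgrid import DockingCube, GridSet
from gridock.gadock import GAParams, apply_genome, ga_search

pocket = g.make_toy_pocket(n_shell_atoms=24, charge_at_base=-1.0, seed=0)
topo, conf = g.make_toy_ligand(n_torsions=1, seed=0)

cube = DockingCube(center=np.array([0.0, 0.0, -1.0]), edge=10.0, spacing=0.5)
grids = GridSet.build(pocket, cube, broadening=0.0)

params = GAParams(population=60, generations=60, n_runs=3, seed=1)
ranked = ga_search(grids, topo, conf, params)

print(f"{len(ranked)} distinct poses (all-atom RMSD >= 1 A apart)")
print(f"{'rank':>4} {'total':>9} {'coulomb':>9} {'vdw':>9} {'desolv':>9} {'entropy':>8}")
for rank, (genome, score) in enumerate(ranked[:5]):
    print(
        f"{rank:>4} {score.total:>9.3f} {score.e_coulomb:>9.3f} "
        f"{score.e_vdw:>9.3f} {score.e_pol:>9.3f} {score.entropy_term:>8.2f}"
    )

best_pose = apply_genome(topo, conf, ranked[0][0])
print("\nbest-pose head-group position (A):", best_pose.coords[0].round(2))
print(
    "The total is the docking score (kcal/mol): the weighted grid energy of\n"
    "the pose plus 0.33 kcal/mol per rotatable torsion.  The charged head\n"
    "sits near the anchor at the pocket base; scores below -5.5 kcal/mol\n"
    "would classify the ligand as a predicted inhibitor."
)
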