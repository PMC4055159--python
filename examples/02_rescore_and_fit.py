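"""Rescore a docked pose with the seven-component empirical score and fit
its coefficients to synthetic activity data.

Relaxes a docked pose in the full force field with GB/SA solvent, prints
the component breakdown and the score under the published urokinase-
trained coefficients, then demonstrates the least-squares coefficient fit
(recovering a known coefficient vector from noiseless synthetic data).
"""

import numpy as np

import gridock as g
from gridock.rescore import (
    UPA_COEFFS_TRAIN50,
    CoefficientVector,
    DiscoreComponents,
    compute_components,
    discore_score,
    fit_coefficients,
    ki_to_dg,
    local_optimize,
)

pocket = g.make_toy_pocket(seed=0)
topo, conf = g.make_toy_ligand(n_torsions=1, seed=0)

# drop the ligand near the pocket mouth and relax it
start = g.Conformer(conf.coords - conf.coords.mean(axis=0) + [0.0, 0.0, -2.0])
relaxed, breakdown = local_optimize(pocket, topo, start)
comps = compute_components(pocket, topo, relaxed)

print("component breakdown at the relaxed pose (kcal/mol):")
print(f"  Coulomb      {comps.dg_coulomb:9.3f}")
print(f"  van der Waals{comps.dg_vdw:9.3f}")
print(f"  polar desolv {comps.dg_pol:9.3f}")
print(f"  nonpolar     {comps.dg_np:9.3f}")
print(f"  strain       {comps.dg_ls:9.3f}   torsions: {comps.n_tors}")
print(f"  rot-tr       {comps.dg_rot_tr:9.3f}")
score = discore_score(comps, UPA_COEFFS_TRAIN50)
print(f"seven-term score: {score:.3f} kcal/mol")
print(f"(for scale: Ki = 10 uM corresponds to {ki_to_dg(1e-5):.2f} kcal/mol)\n")

# coefficient fitting: recover a known k from synthetic components
rng = np.random.default_rng(0)
k_true = CoefficientVector(np.array([0.03, 0.13, 0.24, -0.04, 0.5, 0.26, 0.04]))
rows = []
for _ in range(30):
    v = rng.normal(0, 3, size=7)
    rows.append(
        DiscoreComponents(v[0], v[1], v[2], v[3], abs(v[4]), int(abs(v[5])) + 1, v[6])
    )
dg = [discore_score(r, k_true) for r in rows]
k_fit = fit_coefficients(rows, dg)
print("fitted coefficients:", np.round(k_fit.k, 6))
print("true coefficients:  ", k_true.k)
print(
    "\nWith noiseless data the least-squares fit recovers the generating\n"
    "coefficients to machine precision; with real affinities the residual\n"
    "reflects the force field's systematic errors."
)
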