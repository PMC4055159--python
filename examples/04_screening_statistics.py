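"""Evaluate a scored screening library: enrichment plot, S_E, ROC AUC.

Reproduces the textbook worked example — 2000 ranked compounds containing
8 known actives, 4 of which appear in the top 200 — and prints the
resulting enrichment-plot point, the area S_E, and the ROC AUC.
"""

import numpy as np

from gridock.screenstats import RankedList, enrichment_curve, pearson, roc_auc

labels = [False] * 2000
for idx in (5, 50, 110, 180):      # actives ranked inside the top 200
    labels[idx] = True
for idx in (420, 800, 1400, 1900):  # actives ranked further down
    labels[idx] = True

ranked = RankedList([(f"cmpd{i}", float(i), act) for i, act in enumerate(labels)])
curve = enrichment_curve(ranked)
point = next(p for p in curve.points if p[0] == 10.0)

print(f"library size {ranked.n_all}, actives {ranked.k_all}")
print(f"E-plot point at 10% screened: ({point[0]:.0f}%, {point[1]:.0f}%)")
print(f"S_E = {curve.s_e:.3f}  ({curve.quality})")
print(f"ROC AUC = {roc_auc(ranked):.3f}")

# correlation of predicted vs experimental binding energies
rng = np.random.default_rng(0)
dg_exp = rng.uniform(-10, -3, size=20)
dg_pred = dg_exp + rng.normal(0, 1.0, size=20)
print(f"Pearson r (predicted vs experimental dG): {pearson(dg_pred, dg_exp):.3f}")
print(
    "\nHalf the actives recovered after screening a tenth of the library is\n"
    "strong early enrichment; S_E > 0.9 counts as excellent and S_E < 0.6\n"
    "as no enrichment."
)
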