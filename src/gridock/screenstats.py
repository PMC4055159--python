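"""Virtual-screening and pose-quality evaluation statistics.

Pose accuracy is measured by all-atom RMSD in the shared docking frame
(no superposition) and graded excellent/good/satisfactory/bad at the
1/2/3 Å boundaries.  Ranking quality is measured by the enrichment plot
(fraction of known actives recovered vs fraction of the ranked library
screened) with its area S_E, by the ROC AUC (rank-sum estimator with tie
correction), and by Pearson correlation of predicted vs experimental
binding energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemio import Conformer

RMSD_BINS = ((1.0, "excellent"), (2.0, "good"), (3.0, "satisfactory"))

# interpretive S_E labels (metadata, not logic): > 0.9 excellent,
# < 0.6 no enrichment
SE_EXCELLENT = 0.9
SE_NO_ENRICHMENT = 0.6


def pose_rmsd(a: Conformer, b: Conformer) -> float:
    """All-atom RMSD (Å) with fixed atom correspondence, no superposition."""
    if a.n_atoms != b.n_atoms:
        raise ValueError("conformers differ in atom count")
    return float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))


def grade_rmsd(rmsd: float) -> str:
    """Four-bin pose quality; boundaries fall into the better bin."""
    if rmsd < 0:
        raise ValueError("RMSD must be non-negative")
    for upper, label in RMSD_BINS:
        if rmsd <= upper:
            return label
    return "bad"


@dataclass
class RankedList:
    """Score-sorted screening result: (ligand id, score, active?) entries."""

    entries: list[tuple[str, float, bool]]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e[1])

    @property
    def n_all(self) -> int:
        return len(self.entries)

    @property
    def k_all(self) -> int:
        return sum(1 for e in self.entries if e[2])


@dataclass
class EPlotCurve:
    """Enrichment plot: (% library screened, % actives found) per prefix."""

    points: list[tuple[float, float]]
    s_e: float

    @property
    def quality(self) -> str:
        if self.s_e > SE_EXCELLENT:
            return "excellent"
        if self.s_e < SE_NO_ENRICHMENT:
            return "no enrichment"
        return "some enrichment"


def enrichment_curve(ranked: RankedList) -> EPlotCurve:
    """Enrichment plot over all prefixes of the score-sorted list.

    For every prefix length N with K actives among them the point
    (100·N/N_all, 100·K/K_all) is recorded; S_E is the area under the
    curve (trapezoid rule, x and y rescaled to [0, 1]).
    """
    n_all, k_all = ranked.n_all, ranked.k_all
    if k_all < 1:
        raise ValueError("enrichment requires at least one active")
    xs, ys = [0.0], [0.0]
    k = 0
    for n, entry in enumerate(ranked.entries, start=1):
        k += int(entry[2])
        xs.append(100.0 * n / n_all)
        ys.append(100.0 * k / k_all)
    s_e = float(np.trapezoid(np.array(ys) / 100.0, np.array(xs) / 100.0))
    return EPlotCurve(points=list(zip(xs, ys)), s_e=s_e)


def roc_auc(ranked: RankedList) -> float:
    """Mann–Whitney (rank-sum) ROC AUC with tie correction.

    Probability that a random active scores better (lower) than a random
    inactive; 1 for perfect separation, 0.5 for label-independent scores.
    """
    scores = np.array([e[1] for e in ranked.entries])
    labels = np.array([e[2] for e in ranked.entries], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    from scipy.stats import rankdata

    # lower score = better prediction of activity, so rank by -score
    ranks = rankdata(-scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def plot_enrichment(curve: EPlotCurve, path: str, title: str = "Enrichment plot"):
    """Render an E-plot to PNG/SVG (optional convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p[0] for p in curve.points]
    ys = [p[1] for p in curve.points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(xs, ys, drawstyle="steps-post")
    ax.plot([0, 100], [0, 100], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("% of ranked library")
    ax.set_ylabel("% of known actives found")
    ax.set_title(f"{title} (S_E = {curve.s_e:.2f})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
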