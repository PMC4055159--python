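"""End-to-end pipelines: virtual screening, redocking benchmark, crossdocking.

These orchestrate the lower modules (grids → GA docking → optional
rescoring → evaluation) over collections of ligands and receptors, skip
and log per-ligand failures rather than aborting, and emit a manifest
(config hash, seeds, version) sufficient to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chemio import Conformer, LigandTopology, Receptor
from .energetics import SolventModel
from .fieldgrid import DockingCube, GridSet
from .gadock import (
    GAParams,
    SCORE_THRESHOLD,
    apply_genome,
    classify_predicted,
    ga_search,
)
from .rescore import (
    KI_THRESHOLD,
    CoefficientVector,
    compute_components,
    discore_score,
)
from .screenstats import RankedList, enrichment_curve, grade_rmsd, pose_rmsd

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (JSON-serializable)."""

    receptor_path: str | None = None
    cube_center: tuple[float, float, float] | None = None
    cube_edge: float = 22.0
    grid_spacing: float = 0.35
    broadening: float = 0.35
    ga: GAParams = field(default_factory=GAParams)
    coefficients: tuple[float, ...] | None = None
    score_threshold: float = SCORE_THRESHOLD
    ki_threshold: float = KI_THRESHOLD
    temperature: float = 298.15
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        ga = GAParams(**raw.pop("ga", {}))
        try:
            cfg = cls(ga=ga, **raw)
        except TypeError as exc:
            raise ValueError(f"invalid config: {exc}") from exc
        return cfg

    def manifest(self) -> dict:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest()[:16],
            "seed": self.seed,
            "ga_seed": self.ga.seed,
            "version": __version__,
        }


@dataclass
class ScreenReport:
    """Per-ligand screening rows plus summary statistics."""

    rows: pd.DataFrame
    failures: list[str]
    manifest: dict
    eplot: object | None = None

    @property
    def n_predicted_inhibitors(self) -> int:
        if self.rows.empty:
            return 0
        return int((self.rows["predicted"] == "inhibitor").sum())


def run_virtual_screen(
    grids: GridSet,
    ligands: Iterable[tuple[str, LigandTopology, Conformer]],
    config: RunConfig | None = None,
    receptor: Receptor | None = None,
    rescore_coeffs: CoefficientVector | None = None,
    actives: set[str] | None = None,
) -> ScreenReport:
    """Dock every library ligand, optionally rescore, and rank by score.

    Per-ligand failures are logged and skipped.  When ``actives`` labels
    are given, an enrichment curve over the final ranking is attached.
    Deterministic for a fixed config seed: ligand k uses GA seed
    ``config.ga.seed + k``.
    """
    config = config or RunConfig()
    rows = []
    failures: list[str] = []
    for k, (name, topo, conf) in enumerate(ligands):
        t0 = time.perf_counter()
        try:
            params = dataclasses.replace(config.ga, seed=config.ga.seed + k)
            ranked = ga_search(grids, topo, conf, params)
            if not ranked:
                raise RuntimeError("GA returned no poses")
            genome, score = ranked[0]
            row = {
                "ligand_id": name,
                "sol_total": score.total,
                "e_coulomb": score.e_coulomb,
                "e_vdw": score.e_vdw,
                "e_pol": score.e_pol,
                "entropy_term": score.entropy_term,
                "predicted": classify_predicted(score.total),
            }
            if rescore_coeffs is not None and receptor is not None:
                pose = apply_genome(topo, conf, genome)
                comps = compute_components(
                    receptor, topo, pose, temperature=config.temperature
                )
                row["discore_total"] = discore_score(comps, rescore_coeffs)
            rows.append(row)
            log.info(
                "screen ligand=%s score=%.3f wall=%.2fs",
                name,
                score.total,
                time.perf_counter() - t0,
            )
        except Exception as exc:  # failures never abort the screen
            log.warning("screen ligand=%s failed: %s", name, exc)
            failures.append(name)
    df = pd.DataFrame(rows)
    if not df.empty:
        sort_col = "discore_total" if "discore_total" in df else "sol_total"
        df = df.sort_values(sort_col, kind="mergesort").reset_index(drop=True)
    eplot = None
    if actives is not None and not df.empty:
        ranked = RankedList(
            [
                (r["ligand_id"], r["sol_total"], r["ligand_id"] in actives)
                for r in df.to_dict("records")
            ]
        )
        if ranked.k_all:
            eplot = enrichment_curve(ranked)
    return ScreenReport(
        rows=df, failures=failures, manifest=config.manifest(), eplot=eplot
    )


def run_redock_benchmark(
    complexes: Sequence[tuple[GridSet, LigandTopology, Conformer | None]],
    config: RunConfig | None = None,
) -> dict:
    """Redock each native ligand and grade best-pose RMSD per complex.

    Complexes without a native reference pose are skipped with a warning.
    Returns per-complex rows and the aggregate percentage in each quality
    bin (excellent/good/satisfactory/bad; bins partition the results).
    """
    config = config or RunConfig()
    per_complex = []
    for k, (grids, topo, native) in enumerate(complexes):
        if native is None:
            log.warning("complex %d: missing native pose, skipped", k)
            continue
        params = dataclasses.replace(config.ga, seed=config.ga.seed + k)
        ranked = ga_search(grids, topo, native, params)
        genome, score = ranked[0]
        pose = apply_genome(topo, native, genome)
        rmsd = pose_rmsd(pose, native)
        per_complex.append(
            {"complex": k, "rmsd": rmsd, "grade": grade_rmsd(rmsd), "score": score.total}
        )
    n = len(per_complex)
    bins = {"excellent": 0, "good": 0, "satisfactory": 0, "bad": 0}
    for row in per_complex:
        bins[row["grade"]] += 1
    percent = {g: (100.0 * c / n if n else 0.0) for g, c in bins.items()}
    return {
        "per_complex": per_complex,
        "counts": bins,
        "percent": percent,
        "n_evaluated": n,
        "manifest": config.manifest(),
    }


def run_crossdock(
    receptors_grids: Sequence[GridSet],
    ligands: Sequence[tuple[str, LigandTopology, Conformer]],
    config: RunConfig | None = None,
) -> dict:
    """Score matrix of every ligand docked into every receptor structure.

    Reports the per-ligand score range (max − min across receptors), the
    sensitivity of the score to the receptor structure used.
    """
    if not receptors_grids or not ligands:
        raise ValueError("crossdock requires nonempty receptor and ligand lists")
    config = config or RunConfig()
    matrix = np.zeros((len(receptors_grids), len(ligands)))
    for i, grids in enumerate(receptors_grids):
        for j, (name, topo, conf) in enumerate(ligands):
            params = dataclasses.replace(
                config.ga, seed=config.ga.seed + i * len(ligands) + j
            )
            ranked = ga_search(grids, topo, conf, params)
            matrix[i, j] = ranked[0][1].total
    ranges = matrix.max(axis=0) - matrix.min(axis=0)
    return {
        "matrix": matrix,
        "ligand_ids": [name for name, _t, _c in ligands],
        "score_range": ranges,
        "manifest": config.manifest(),
    }


def apply_external_enthalpy_labels(
    table: pd.DataFrame, enthalpy_col: str = "enthalpy", threshold: float = -40.0
) -> pd.DataFrame:
    """Label rows by an externally computed (quantum-chemistry) enthalpy.

    No quantum chemistry is performed here: the column is imported from an
    external package's output and thresholded (default −40 kcal/mol).
    """
    out = table.copy()
    out["enthalpy_label"] = np.where(
        out[enthalpy_col] < threshold, "inhibitor", "non-inhibitor"
    )
    return out
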