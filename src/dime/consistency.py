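"""Jackknife stability analysis of DIME results.

The procedure reruns DIME many times on random 70% subsamples of either the
disease genes (to test the stability of the top cells) or the cell types
(to test the stability of the top genes), counts how often each item
reappears as a top member of the top cluster, and correlates those counts
with the original run's scores (Pearson). A significant positive
correlation says the original top members are not an artifact of the
particular gene/cell sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DimeError, UsageError
from .io import Disease, DiseaseGeneNetwork, ImmunomeMatrix
from .core import DimeConfig, DimeResult, run_dime

logger = logging.getLogger(__name__)

__all__ = ["JackknifeResult", "jackknife_run", "consistency_test"]


@dataclass
class JackknifeResult:
    disease_id: str
    mode: str  # "subsample_genes" (tests DACs) | "subsample_cells" (tests DAGs)
    n_sim: int
    n_effective: int  # simulations actually scored (skips excluded)
    frac: float
    occurrence: dict[str, int]
    tracked_scores: dict[str, float]  # original-run scores of the tracked items
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    significant: bool = False


def _subsample_network(
    net: DiseaseGeneNetwork, disease_id: str, genes: set[str]
) -> DiseaseGeneNetwork:
    d = net.diseases[disease_id]
    sub = DiseaseGeneNetwork()
    sub.diseases[disease_id] = Disease(disease_id, d.name, set(genes))
    return sub


def _subsample_immunome(imm: ImmunomeMatrix, cells: list[str]) -> ImmunomeMatrix:
    idx = [imm.cell_ids.index(c) for c in cells]
    return ImmunomeMatrix(list(imm.gene_ids), cells, imm.values[:, idx])


def jackknife_run(
    imm: ImmunomeMatrix,
    net: DiseaseGeneNetwork,
    disease_id: str,
    mode: str = "subsample_genes",
    n_sim: int = 1000,
    frac: float = 0.70,
    base_seed: int = 0,
    seed: int = 0,
    config: DimeConfig = DimeConfig(),
    original: DimeResult | None = None,
    top_n_dags: int = 10,
) -> JackknifeResult:
    """Run ``n_sim`` jackknife simulations at subsample fraction ``frac``.

    Each simulation draws floor(frac * n) items without replacement (seed =
    ``base_seed`` + simulation index; the inner DIME run keeps the caller's
    ``seed``), reruns DIME with k reselected, and counts the top cluster's
    top DACs (gene mode) or its ``top_n_dags`` highest-scoring DAGs (cell
    mode). Subsamples falling below ``config.min_genes`` are skipped and the
    denominator adjusted.
    """
    if mode not in ("subsample_genes", "subsample_cells"):
        raise UsageError(f"unknown jackknife mode {mode!r}")
    if not (0 < frac <= 1):
        raise DimeError("frac must be in (0, 1]")
    if original is None:
        original = run_dime(imm, net, disease_id, seed=seed, config=config)

    if mode == "subsample_genes":
        items = sorted(net.diseases[disease_id].genes & set(imm.gene_ids))
        tracked = dict(original.top_cluster.dac_scores)
    else:
        items = list(imm.cell_ids)
        dag = original.top_cluster.dag_scores
        top = sorted(dag, key=lambda g: (-dag[g], g))[:top_n_dags]
        tracked = {g: dag[g] for g in top}

    n_take = int(np.floor(frac * len(items)))
    occurrence: dict[str, int] = {i: 0 for i in tracked}
    n_effective = 0
    for sim in range(n_sim):
        rng = np.random.default_rng(int(base_seed) + sim)
        chosen = sorted(rng.choice(len(items), size=n_take, replace=False))
        subset = [items[i] for i in chosen]
        try:
            if mode == "subsample_genes":
                if len(subset) < config.min_genes:
                    raise DimeError("subsample below min_genes")
                sub_net = _subsample_network(net, disease_id, set(subset))
                res = run_dime(imm, sub_net, disease_id, seed=seed, config=config)
                found = res.top_cluster.top_dacs
            else:
                if len(subset) < 2:
                    raise DimeError("subsample below 2 cells")
                sub_imm = _subsample_immunome(imm, subset)
                res = run_dime(sub_imm, net, disease_id, seed=seed, config=config)
                dscores = res.top_cluster.dag_scores
                found = set(
                    sorted(dscores, key=lambda g: (-dscores[g], g))[:top_n_dags]
                )
        except DimeError as exc:
            logger.warning("simulation %d skipped: %s", sim, exc)
            continue
        n_effective += 1
        for item in found:
            if item in occurrence:
                occurrence[item] += 1
    jk = JackknifeResult(
        disease_id=disease_id, mode=mode, n_sim=n_sim, n_effective=n_effective,
        frac=frac, occurrence=occurrence, tracked_scores=tracked,
    )
    r, p, sig = consistency_test(tracked, occurrence)
    return replace(jk, pearson_r=r, pearson_p=p, significant=sig)


def consistency_test(
    scores: dict[str, float], occurrence: dict[str, int]
) -> tuple[float, float, bool]:
    """Pearson correlation between original scores and jackknife occurrence
    counts (items never observed count 0); two-sided p from the
    t-distribution with n-2 df; significant iff p <= 0.05."""
    keys = sorted(scores)
    if len(keys) < 3:
        raise DimeError("consistency test needs at least 3 items")
    x = np.array([scores[k] for k in keys], dtype=float)
    y = np.array([occurrence.get(k, 0) for k in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "zero variance in scores or counts: correlation undefined",
            stacklevel=2,
        )
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), bool(p <= 0.05)
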