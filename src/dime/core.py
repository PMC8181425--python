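"""The DIME procedure: extract the disease expression matrix, factor it,
score disease-associated cells (DACs) and genes (DAGs), rank clusters by
Frobenius norm, and assemble the bipartite cell-gene network.

For a disease D with gene set G_D, the disease matrix X_D is the reference
expression matrix restricted to G_D (genes x all cell types). KL-NMF gives
X_D ~= W H; for each cluster i the column w_i carries gene weights and the
row h_i cell weights. Scores are w_i / max(w_i) and h_i / max(h_i), top
members are those at or above the 75th percentile of their cluster's
scores, and clusters are ranked by ||w_i h_i^T||_F = ||w_i|| * ||h_i||
(rank 1 = the top cluster, the component that captures most of X_D).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DimeError
from .io import DiseaseGeneNetwork, ImmunomeMatrix
from . import nmf

logger = logging.getLogger(__name__)

__all__ = [
    "DimeConfig",
    "DiseaseMatrix",
    "ClusterResult",
    "DimeResult",
    "Edge",
    "DimeNetwork",
    "extract_disease_matrix",
    "scale_scores",
    "top_percentile_select",
    "rank_clusters",
    "run_dime",
    "build_dime_network",
    "prune_for_display",
]


@dataclass(frozen=True)
class DimeConfig:
    """Tunable parameters of a DIME run.

    n_restarts        best-of restarts for the scored factorization
    n_runs_consensus  restarts per k in consensus model-order selection
    k_min / k_max     candidate cluster numbers (capped by matrix shape)
    percentile        membership quantile (0.75 = top 25th percentile)
    min_genes         minimum mappable disease genes to attempt a run

    Consensus restarts used for model-order selection only need the cluster
    assignment pattern, which stabilises long before full convergence, so
    they run under a tighter iteration cap (``consensus_max_iter``) than the
    scored factorization.
    """

    n_restarts: int = 30
    n_runs_consensus: int = 30
    k_min: int = 2
    k_max: int = 7
    max_iter: int = 2000
    consensus_max_iter: int = 300
    tol: float = 1e-6
    percentile: float = 0.75
    min_genes: int = 15


@dataclass
class DiseaseMatrix:
    disease_id: str
    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    n_dropped_genes: int = 0


@dataclass
class ClusterResult:
    rank: int
    cluster_index: int
    frobenius_weight: float
    dac_scores: dict[str, float]
    dag_scores: dict[str, float]
    top_dacs: set[str]
    top_dags: set[str]


@dataclass
class DimeResult:
    disease_id: str
    k: int
    clusters: list[ClusterResult]
    factorization: nmf.Factorization
    percentile_threshold: float = 0.75
    k_profile: dict[int, float] | None = None

    @property
    def top_cluster(self) -> ClusterResult:
        return self.clusters[0]

    def to_json(self, path=None) -> str:
        payload = {
            "disease_id": self.disease_id,
            "k": self.k,
            "percentile_threshold": self.percentile_threshold,
            "k_profile": self.k_profile,
            "seed": self.factorization.seed,
            "n_iter": self.factorization.n_iter,
            "divergence": self.factorization.divergence,
            "clusters": [
                {
                    "rank": c.rank,
                    "cluster_index": c.cluster_index,
                    "frobenius_weight": c.frobenius_weight,
                    "dac_scores": dict(sorted(c.dac_scores.items())),
                    "dag_scores": dict(sorted(c.dag_scores.items())),
                    "top_dacs": sorted(c.top_dacs),
                    "top_dags": sorted(c.top_dags),
                }
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class Edge:
    cell: str
    gene: str
    cluster_rank: int
    dac_score: float
    dag_score: float
    median_expression: float
    druggable: bool = False
    drugs: tuple[str, ...] = ()


@dataclass
class DimeNetwork:
    disease_id: str
    edges: list[Edge] = field(default_factory=list)

    def edge_pairs(self) -> set[tuple[str, str]]:
        """(cell, gene) pairs ignoring cluster rank."""
        return {(e.cell, e.gene) for e in self.edges}

    def cells(self) -> set[str]:
        return {e.cell for e in self.edges}

    def genes(self) -> set[str]:
        return {e.gene for e in self.edges}


# ---------------------------------------------------------------------------


def extract_disease_matrix(
    imm: ImmunomeMatrix,
    net: DiseaseGeneNetwork,
    disease_id: str,
    min_genes: int = 15,
) -> DiseaseMatrix:
    """Restrict the reference matrix to the disease's genes (immunome row
    order preserved); genes absent from the reference are dropped and
    counted."""
    if disease_id not in net:
        raise DimeError(f"unknown disease {disease_id!r}")
    wanted = net.diseases[disease_id].genes
    rows = [i for i, g in enumerate(imm.gene_ids) if g in wanted]
    n_dropped = len(wanted) - len(rows)
    if n_dropped:
        logger.info("disease %s: %d gene(s) not in the immunome", disease_id, n_dropped)
    if len(rows) < min_genes:
        raise DimeError(
            f"too few mappable DAGs for {disease_id}: {len(rows)} < min_genes={min_genes}"
        )
    return DiseaseMatrix(
        disease_id=disease_id,
        gene_ids=[imm.gene_ids[i] for i in rows],
        cell_ids=list(imm.cell_ids),
        values=imm.values[rows, :].copy(),
        n_dropped_genes=n_dropped,
    )


def scale_scores(v: np.ndarray) -> np.ndarray:
    """Max-scale a non-negative vector to [0, 1] (zeros stay zero)."""
    v = np.asarray(v, dtype=float)
    m = v.max() if v.size else 0.0
    if m <= 0:
        raise DimeError("cannot scale an all-zero score vector")
    return v / m


def top_percentile_select(scores: dict[str, float], q: float = 0.75) -> set[str]:
    """Ids whose score is at or above the q-quantile of the score multiset
    (linear interpolation between order statistics). Never empty: the
    maximum always qualifies."""
    if not scores:
        raise DimeError("empty score map")
    if not (0 < q < 1):
        raise DimeError("q must be in (0, 1)")
    values = np.fromiter(scores.values(), dtype=float)
    threshold = float(np.quantile(values, q, method="linear"))
    return {i for i, s in scores.items() if s >= threshold}


def rank_clusters(f: nmf.Factorization) -> list[tuple[int, float]]:
    """(cluster_index, ||w_i h_i^T||_F) sorted by non-increasing weight; the
    rank-1 identity ||w h^T||_F = ||w||_2 ||h||_2 avoids materialising outer
    products. Ties keep the lower cluster index first."""
    weights = np.linalg.norm(f.W, axis=0) * np.linalg.norm(f.H, axis=1)
    order = np.argsort(-weights, kind="stable")
    return [(int(i), float(weights[i])) for i in order]


def _best_factorization(
    X: np.ndarray, k: int, seed: int, config: DimeConfig
) -> nmf.Factorization:
    """Best-of-restarts: the factorization with the lowest final divergence."""
    best: nmf.Factorization | None = None
    for i in range(config.n_restarts):
        f = nmf.nmf_kl(X, k, seed=seed + i, max_iter=config.max_iter, tol=config.tol)
        if best is None or f.divergence < best.divergence:
            best = f
    assert best is not None
    return best


def run_dime(
    imm: ImmunomeMatrix,
    net: DiseaseGeneNetwork,
    disease_id: str,
    k: int | None = None,
    seed: int = 0,
    config: DimeConfig = DimeConfig(),
) -> DimeResult:
    """Full DIME run for one disease; deterministic given (seed, config)."""
    dm = extract_disease_matrix(imm, net, disease_id, min_genes=config.min_genes)
    X = dm.values
    k_profile = None
    if k is None:
        hi = min(config.k_max, min(X.shape) - 1)
        k_range = list(range(config.k_min, hi + 1))
        k_profile = nmf.cophenetic_profile(
            X, k_range=k_range, n_runs=config.n_runs_consensus,
            base_seed=seed, max_iter=config.consensus_max_iter, tol=config.tol,
        )
        k = nmf._smallest_k_at_max(k_profile)
    f = _best_factorization(X, k, seed, config)
    ranking = rank_clusters(f)
    clusters: list[ClusterResult] = []
    for rank, (ci, weight) in enumerate(ranking, start=1):
        dac = dict(zip(dm.cell_ids, scale_scores(f.H[ci, :])))
        dag = dict(zip(dm.gene_ids, scale_scores(f.W[:, ci])))
        clusters.append(
            ClusterResult(
                rank=rank,
                cluster_index=ci,
                frobenius_weight=weight,
                dac_scores=dac,
                dag_scores=dag,
                top_dacs=top_percentile_select(dac, config.percentile),
                top_dags=top_percentile_select(dag, config.percentile),
            )
        )
    return DimeResult(
        disease_id=disease_id, k=k, clusters=clusters, factorization=f,
        percentile_threshold=config.percentile, k_profile=k_profile,
    )


def build_dime_network(res: DimeResult, imm: ImmunomeMatrix) -> DimeNetwork:
    """Complete bipartite top_dacs x top_dags edges per cluster, tagged with
    the cluster rank and annotated with scores and reference expression."""
    gidx = imm.gene_index()
    cidx = {c: j for j, c in enumerate(imm.cell_ids)}
    edges: list[Edge] = []
    for c in res.clusters:
        cells = sorted(c.top_dacs)
        for g in sorted(c.top_dags):
            med = float(np.median([imm.values[gidx[g], cidx[cc]] for cc in cells]))
            for cc in cells:
                edges.append(
                    Edge(
                        cell=cc, gene=g, cluster_rank=c.rank,
                        dac_score=float(c.dac_scores[cc]),
                        dag_score=float(c.dag_scores[g]),
                        median_expression=med,
                    )
                )
    return DimeNetwork(disease_id=res.disease_id, edges=edges)


def prune_for_display(
    nw: DimeNetwork,
    imm: ImmunomeMatrix,
    max_dags: int = 50,
    min_expression: float = 5.0,
) -> DimeNetwork:
    """Per cluster keep at most ``max_dags`` genes by descending DAG score,
    then drop genes whose median expression across the cluster's cells is at
    or below ``min_expression``. Cells are untouched."""
    gidx = imm.gene_index()
    cidx = {c: j for j, c in enumerate(imm.cell_ids)}
    by_rank: dict[int, list[Edge]] = {}
    for e in nw.edges:
        by_rank.setdefault(e.cluster_rank, []).append(e)
    kept: list[Edge] = []
    for rank, edges in sorted(by_rank.items()):
        cells = sorted({e.cell for e in edges})
        gene_score = {}
        for e in edges:
            gene_score[e.gene] = e.dag_score
        top = sorted(gene_score, key=lambda g: (-gene_score[g], g))[:max_dags]
        for g in top:
            med = float(np.median([imm.values[gidx[g], cidx[cc]] for cc in cells]))
            if med <= min_expression:
                continue
            kept.extend(e for e in edges if e.gene == g)
    return DimeNetwork(disease_id=nw.disease_id, edges=kept)
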