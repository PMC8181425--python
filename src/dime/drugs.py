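"""Drug-gene overlay: annotate bipartite networks with druggability and
nominate repurposing candidates from statistically significant common
cell-gene networks.

A repurposing candidate is a druggable gene that appears (as the endpoint
of a common edge) in at least one significant (Fisher p <= alpha) common
network between two diseases; a candidate is additionally flagged
"top-cluster target" when it is a top gene of the rank-1 cluster in every
disease it is listed for — the strictest evidence tier.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import pandas as pd

from .io import DrugGeneNetwork, DrugRecord
from .core import DimeNetwork, DimeResult
from .compare import PairwiseComparison

logger = logging.getLogger(__name__)

__all__ = ["annotate_druggable", "merge_drug_sources", "repurposing_candidates"]


def annotate_druggable(
    nw: DimeNetwork, dgn: DrugGeneNetwork, approved_only: bool = False
) -> DimeNetwork:
    """Return a copy of the network whose gene nodes carry a druggable flag
    and their drug list; edges and scores are untouched."""
    edges = []
    for e in nw.edges:
        recs = dgn.drugs_for(e.gene, approved_only=approved_only)
        edges.append(
            replace(e, druggable=bool(recs), drugs=tuple(r.drug for r in recs))
        )
    return DimeNetwork(disease_id=nw.disease_id, edges=edges)


def merge_drug_sources(tables: list[DrugGeneNetwork]) -> DrugGeneNetwork:
    """Union of several drug-gene tables; duplicate (gene, drug) pairs keep
    one record per source (provenance preserved)."""
    out = DrugGeneNetwork()
    for t in tables:
        for gene, recs in t.targets.items():
            for r in recs:
                out.add(gene, DrugRecord(r.drug, r.source, r.approved))
    return out


def repurposing_candidates(
    comparison: PairwiseComparison,
    dime_results: dict[str, DimeResult],
    dgn: DrugGeneNetwork,
    alpha: float = 0.05,
    approved_only: bool = True,
) -> pd.DataFrame:
    """Candidate table: druggable genes found in significant common
    networks, with the diseases they connect, their drugs, and the
    top-cluster flag. Sorted by number of diseases (desc) then gene."""
    per_gene_diseases: dict[str, set[str]] = {}
    n_significant = 0
    for (a, b), overlap in comparison.results.items():
        if overlap.fisher_p > alpha:
            continue
        n_significant += 1
        for gene in comparison.common[(a, b)].genes():
            if dgn.drugs_for(gene, approved_only=approved_only):
                per_gene_diseases.setdefault(gene, set()).update((a, b))
    if n_significant == 0:
        logger.warning("no significant common networks at alpha=%.3g", alpha)
    rows = []
    for gene, diseases in per_gene_diseases.items():
        recs = dgn.drugs_for(gene, approved_only=approved_only)
        top_flag = all(
            gene in dime_results[d].top_cluster.top_dags
            for d in diseases
            if d in dime_results
        )
        rows.append(
            {
                "gene": gene,
                "diseases": ";".join(sorted(diseases)),
                "n_diseases": len(diseases),
                "drugs": ";".join(sorted({r.drug for r in recs})),
                "sources": ";".join(sorted({r.source for r in recs})),
                "top_cluster_target": top_flag,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "diseases", "n_diseases", "drugs", "sources", "top_cluster_target"],
    )
    if len(df):
        df = df.sort_values(
            ["n_diseases", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
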