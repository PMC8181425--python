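"""Pairwise disease comparison: common cell-gene networks, Jaccard indices
and one-sided Fisher's exact (hypergeometric enrichment) tests.

Two diseases are compared through the (cell, gene) edge sets of their
bipartite networks (or through plain gene sets). The Jaccard index measures
overlap size; the Fisher test asks whether the observed overlap is larger
than expected when the two sets are drawn independently from a stated
universe. p-values are reported raw (no multiplicity correction) so users
can adjust as they see fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

from .errors import DimeError
from .core import DimeNetwork

__all__ = [
    "OverlapResult",
    "CommonEdge",
    "CommonNetwork",
    "PairwiseComparison",
    "jaccard_index",
    "fisher_overlap_test",
    "significance_label",
    "common_cell_gene_network",
    "pairwise_comparison",
    "compare_networks",
]


def jaccard_index(A: set, B: set) -> float:
    """|A n B| / |A u B|; errors when both sets are empty."""
    union = A | B
    if not union:
        raise DimeError("Jaccard index undefined for two empty sets")
    return len(A & B) / len(union)


def fisher_overlap_test(A: set, B: set, universe_size: int) -> float:
    """One-sided enrichment p-value P(X >= |A n B|) for
    X ~ Hypergeom(N=universe_size, K=|A|, n=|B|)."""
    if universe_size < len(A) or universe_size < len(B):
        raise DimeError("universe smaller than one of the sets")
    m = len(A & B)
    # sf(m-1) = P(X >= m)
    return float(hypergeom.sf(m - 1, universe_size, len(A), len(B)))


def significance_label(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class OverlapResult:
    disease_a: str
    disease_b: str
    item_kind: str  # "genes" | "cell_gene_pairs"
    intersection: set
    jaccard: float
    fisher_p: float
    universe_size: int

    @property
    def significance_label(self) -> str:
        return significance_label(self.fisher_p)


@dataclass(frozen=True)
class CommonEdge:
    cell: str
    gene: str
    rank_a: int
    rank_b: int


@dataclass
class CommonNetwork:
    disease_a: str
    disease_b: str
    edges: list[CommonEdge] = field(default_factory=list)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.cell, e.gene) for e in self.edges}

    def genes(self) -> set[str]:
        return {e.gene for e in self.edges}

    def cells(self) -> set[str]:
        return {e.cell for e in self.edges}


def common_cell_gene_network(
    nwA: DimeNetwork, nwB: DimeNetwork, universe_size: int
) -> tuple[CommonNetwork, OverlapResult]:
    """Intersect two bipartite networks on (cell, gene) pairs (cluster rank
    ignored for membership, but each common edge is annotated with its best
    rank in either network)."""
    pairs_a = nwA.edge_pairs()
    pairs_b = nwB.edge_pairs()
    common = pairs_a & pairs_b
    rank_a = {}
    for e in nwA.edges:
        key = (e.cell, e.gene)
        if key in common:
            rank_a[key] = min(rank_a.get(key, e.cluster_rank), e.cluster_rank)
    rank_b = {}
    for e in nwB.edges:
        key = (e.cell, e.gene)
        if key in common:
            rank_b[key] = min(rank_b.get(key, e.cluster_rank), e.cluster_rank)
    net = CommonNetwork(
        disease_a=nwA.disease_id,
        disease_b=nwB.disease_id,
        edges=[
            CommonEdge(cell=c, gene=g, rank_a=rank_a[(c, g)], rank_b=rank_b[(c, g)])
            for c, g in sorted(common)
        ],
    )
    overlap = OverlapResult(
        disease_a=nwA.disease_id,
        disease_b=nwB.disease_id,
        item_kind="cell_gene_pairs",
        intersection=common,
        jaccard=jaccard_index(pairs_a, pairs_b) if (pairs_a | pairs_b) else 0.0,
        fisher_p=fisher_overlap_test(pairs_a, pairs_b, universe_size),
        universe_size=universe_size,
    )
    return net, overlap


def pairwise_comparison(
    items: dict[str, set], universe_size: int, item_kind: str = "genes"
) -> dict[tuple[str, str], OverlapResult]:
    """All unordered pairwise overlaps between per-disease item sets."""
    if len(items) < 2:
        raise DimeError("pairwise comparison needs at least two diseases")
    out: dict[tuple[str, str], OverlapResult] = {}
    for a, b in combinations(sorted(items), 2):
        out[(a, b)] = OverlapResult(
            disease_a=a,
            disease_b=b,
            item_kind=item_kind,
            intersection=items[a] & items[b],
            jaccard=jaccard_index(items[a], items[b]),
            fisher_p=fisher_overlap_test(items[a], items[b], universe_size),
            universe_size=universe_size,
        )
    return out


@dataclass
class PairwiseComparison:
    """All-pairs comparison of DIME networks on (cell, gene) edges."""

    results: dict[tuple[str, str], OverlapResult]
    common: dict[tuple[str, str], CommonNetwork]
    universe_size: int

    def get(self, a: str, b: str) -> OverlapResult:
        key = (a, b) if (a, b) in self.results else (b, a)
        return self.results[key]

    def long_table(self) -> pd.DataFrame:
        rows = [
            {
                "disease_a": r.disease_a,
                "disease_b": r.disease_b,
                "item_kind": r.item_kind,
                "overlap": len(r.intersection),
                "jaccard": r.jaccard,
                "fisher_p": r.fisher_p,
                "significance": r.significance_label,
                "universe_size": r.universe_size,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows).sort_values(["disease_a", "disease_b"]).reset_index(drop=True)

    def matrix_table(self) -> pd.DataFrame:
        """Square table: Jaccard below the diagonal, significance stars above,
        1.0 on the diagonal."""
        ids = sorted({d for pair in self.results for d in pair})
        m = pd.DataFrame("", index=ids, columns=ids, dtype=object)
        for d in ids:
            m.loc[d, d] = "1.0"
        for (a, b), r in self.results.items():
            lo, hi = sorted([a, b])
            m.loc[hi, lo] = f"{r.jaccard:.4g}"
            m.loc[lo, hi] = r.significance_label
        return m


def compare_networks(
    networks: dict[str, DimeNetwork], universe_size: int
) -> PairwiseComparison:
    """All-pairs common cell-gene networks with Jaccard + Fisher statistics.

    ``universe_size`` is typically |immunome cells| x |union of disease
    genes| for edge comparisons.
    """
    if len(networks) < 2:
        raise DimeError("need at least two networks")
    results: dict[tuple[str, str], OverlapResult] = {}
    common: dict[tuple[str, str], CommonNetwork] = {}
    for a, b in combinations(sorted(networks), 2):
        net, overlap = common_cell_gene_network(networks[a], networks[b], universe_size)
        results[(a, b)] = overlap
        common[(a, b)] = net
    return PairwiseComparison(results=results, common=common, universe_size=universe_size)
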