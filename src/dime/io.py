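"""Readers and writers for every external artifact.

All tabular formats are UTF-8, tab-delimited TSV with a header line (the one
exception is the ``gene_list`` dialect: one bare gene symbol per line).
Gene identifiers are opaque, case-sensitive symbols; no alias mapping is
attempted. Readers never silently drop rows — every rejected record is
counted and reported through the module logger.

Containers
----------
:class:`ImmunomeMatrix`
    genes x cell-types matrix of non-negative expression values
    (log2(CPM+1) scale); the reference expression context.
:class:`DiseaseGeneNetwork`
    disease (CUI + name) -> set of associated gene symbols.
:class:`DrugGeneNetwork`
    gene symbol -> drug-interaction records (drug, source, approved flag).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "ImmunomeMatrix",
    "Disease",
    "DiseaseGeneNetwork",
    "DrugRecord",
    "DrugGeneNetwork",
    "read_immunome",
    "write_immunome",
    "read_disease_gene_table",
    "write_disease_gene_table",
    "read_drug_gene_table",
    "write_drug_gene_table",
    "write_network",
    "read_network",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ImmunomeMatrix:
    """Dense genes x cell-types expression matrix, log2(CPM+1)-scale.

    Invariants (checked on construction): unique non-empty gene and cell
    identifiers, no negative entries, at least 2 genes and 2 cells.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(self.gene_ids) < 2 or len(self.cell_ids) < 2:
            raise FormatError("expression matrix needs at least 2 genes and 2 cells")
        for ids, kind in ((self.gene_ids, "gene"), (self.cell_ids, "cell")):
            if any(not s for s in ids):
                raise FormatError(f"empty {kind} identifier")
            seen: set[str] = set()
            for s in ids:
                if s in seen:
                    raise FormatError(f"duplicate {kind} identifier {s!r}")
                seen.add(s)
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at ({self.gene_ids[i]}, {self.cell_ids[j]})"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value {self.values[i, j]} at "
                f"({self.gene_ids[i]}, {self.cell_ids[j]})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImmunomeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImmunomeMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )


@dataclass
class Disease:
    disease_id: str
    name: str
    genes: set[str]
    scores: dict[str, float] | None = None


@dataclass
class DiseaseGeneNetwork:
    """Map from disease CUI to its associated gene set (the disease's DAGs)."""

    diseases: dict[str, Disease] = field(default_factory=dict)

    def add(self, disease_id: str, name: str, gene: str, score: float | None = None) -> None:
        d = self.diseases.setdefault(disease_id, Disease(disease_id, name, set()))
        d.genes.add(gene)
        if score is not None:
            if d.scores is None:
                d.scores = {}
            d.scores[gene] = score

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for d in self.diseases.values():
            out |= d.genes
        return out

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.diseases

    def __len__(self) -> int:
        return len(self.diseases)


@dataclass(frozen=True)
class DrugRecord:
    drug: str
    source: str
    approved: bool


@dataclass
class DrugGeneNetwork:
    """Gene symbol -> set of drug-interaction records."""

    targets: dict[str, set[DrugRecord]] = field(default_factory=dict)

    def add(self, gene: str, record: DrugRecord) -> None:
        if not record.drug:
            raise FormatError(f"empty drug name for gene {gene!r}")
        self.targets.setdefault(gene, set()).add(record)

    def drugs_for(self, gene: str, approved_only: bool = False) -> list[DrugRecord]:
        recs = self.targets.get(gene, set())
        if approved_only:
            recs = {r for r in recs if r.approved}
        return sorted(recs, key=lambda r: (r.drug, r.source))

    def __contains__(self, gene: str) -> bool:
        return gene in self.targets

    def __len__(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# expression matrices


def read_immunome(path, fmt: str = "tsv") -> ImmunomeMatrix:
    """Read a genes x cell-types expression TSV (header = cell names, first
    column = gene symbols). Row and column order are preserved."""
    if fmt != "tsv":
        raise UsageError(f"unknown immunome format {fmt!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty expression matrix in {path}")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene identifier {dup[0]!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"missing/non-numeric value at ({df.index[i]}, {df.columns[j]})"
        )
    return ImmunomeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_immunome(imm: ImmunomeMatrix, path) -> None:
    imm.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# disease-gene tables

_DISGENET_COLUMNS = ("geneSymbol", "diseaseId", "diseaseName")


def read_disease_gene_table(
    path,
    dialect: str = "disgenet_curated",
    disease_filter: set[str] | None = None,
    disease_id: str = "custom",
    disease_name: str = "custom",
) -> DiseaseGeneNetwork:
    """Read disease-gene associations.

    Dialects:

    ``disgenet_curated``
        any TSV containing at least the columns geneSymbol, diseaseId and
        diseaseName (any order; extra columns ignored; an optional ``score``
        column is kept as the per-gene association weight).
    ``two_column``
        header + rows of (disease_id, gene).
    ``gene_list``
        one gene symbol per line, no header, for a single disease named by
        ``disease_id`` / ``disease_name``.

    ``disease_filter`` restricts the result to the given CUIs.
    """
    net = DiseaseGeneNetwork()
    n_in = n_rejected = 0
    if dialect == "disgenet_curated":
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        missing = [c for c in _DISGENET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"missing required column(s) {missing} in {path}; "
                f"expected at least {list(_DISGENET_COLUMNS)}"
            )
        has_score = "score" in df.columns
        for row in df.itertuples(index=False):
            n_in += 1
            gene = getattr(row, "geneSymbol")
            did = getattr(row, "diseaseId")
            name = getattr(row, "diseaseName")
            if not isinstance(gene, str) or not gene or not isinstance(did, str):
                n_rejected += 1
                continue
            if disease_filter is not None and did not in disease_filter:
                continue
            score = None
            if has_score:
                try:
                    score = float(getattr(row, "score"))
                except (TypeError, ValueError):
                    score = None
            net.add(did, name if isinstance(name, str) else did, gene, score)
    elif dialect == "two_column":
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        if df.shape[1] < 2:
            raise FormatError(f"two_column dialect needs 2 columns in {path}")
        for row in df.itertuples(index=False):
            n_in += 1
            did, gene = row[0], row[1]
            if not isinstance(did, str) or not isinstance(gene, str) or not gene:
                n_rejected += 1
                continue
            if disease_filter is not None and did not in disease_filter:
                continue
            net.add(did, did, gene)
    elif dialect == "gene_list":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                n_in += 1
                gene = line.strip()
                if not gene:
                    n_rejected += 1
                    continue
                net.add(disease_id, disease_name, gene)
    else:
        raise UsageError(f"unknown disease-gene dialect {dialect!r}")
    if n_rejected:
        logger.warning("%s: rejected %d of %d rows", path, n_rejected, n_in)
    for d in net.diseases.values():
        if not d.genes:
            raise FormatError(f"disease {d.disease_id} has an empty gene set")
    return net


def write_disease_gene_table(net: DiseaseGeneNetwork, path) -> None:
    """Write in the disgenet_curated dialect (round-trips with the reader)."""
    rows = []
    for did in sorted(net.diseases):
        d = net.diseases[did]
        for g in sorted(d.genes):
            rows.append(
                {
                    "geneSymbol": g,
                    "diseaseId": did,
                    "diseaseName": d.name,
                    "score": "" if d.scores is None or g not in d.scores else d.scores[g],
                }
            )
    pd.DataFrame(rows, columns=["geneSymbol", "diseaseId", "diseaseName", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# drug-gene tables

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_approved(raw: str, path) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(f"unparseable approved flag {raw!r} in {path}")


def read_drug_gene_table(path) -> DrugGeneNetwork:
    """Read a TSV with columns gene, drug, source, approved."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    required = ["gene", "drug", "source", "approved"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    dgn = DrugGeneNetwork()
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene")
        drug = getattr(row, "drug")
        if not isinstance(gene, str) or not isinstance(drug, str):
            raise FormatError(f"missing gene/drug value in {path}")
        dgn.add(
            gene,
            DrugRecord(drug, str(getattr(row, "source")), _parse_approved(getattr(row, "approved"), path)),
        )
    return dgn


def write_drug_gene_table(dgn: DrugGeneNetwork, path) -> None:
    rows = []
    for gene in sorted(dgn.targets):
        for rec in dgn.drugs_for(gene):
            rows.append(
                {"gene": gene, "drug": rec.drug, "source": rec.source,
                 "approved": "true" if rec.approved else "false"}
            )
    pd.DataFrame(rows, columns=["gene", "drug", "source", "approved"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# bipartite networks

_EDGE_COLUMNS = [
    "cell", "gene", "cluster_rank", "dac_score", "dag_score",
    "median_expression", "druggable", "drugs",
]


def _edges_frame(network) -> pd.DataFrame:
    rows = []
    for e in sorted(network.edges, key=lambda e: (e.cluster_rank, e.cell, e.gene)):
        rows.append(
            {
                "cell": e.cell,
                "gene": e.gene,
                "cluster_rank": e.cluster_rank,
                "dac_score": e.dac_score,
                "dag_score": e.dag_score,
                "median_expression": e.median_expression,
                "druggable": "true" if e.druggable else "false",
                "drugs": ";".join(e.drugs),
            }
        )
    return pd.DataFrame(rows, columns=_EDGE_COLUMNS)


def write_network(network, path, fmt: str = "edge_tsv") -> None:
    """Write a bipartite cell-gene network as edge TSV, GraphML or JSON.

    edge_tsv round-trips losslessly through :func:`read_network`.
    """
    if fmt == "edge_tsv":
        # default float formatting is shortest-roundtrip: lossless read-back
        _edges_frame(network).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph(disease_id=getattr(network, "disease_id", ""))
        for e in network.edges:
            cnode, gnode = f"cell:{e.cell}", f"gene:{e.gene}"
            g.add_node(cnode, kind="cell", label=e.cell, dac_score=float(e.dac_score))
            g.add_node(
                gnode, kind="gene", label=e.gene, dag_score=float(e.dag_score),
                median_expression=float(e.median_expression),
                druggable=bool(e.druggable), drugs=";".join(e.drugs),
            )
            g.add_edge(cnode, gnode, cluster_rank=int(e.cluster_rank))
        nx.write_graphml(g, path)
    elif fmt == "json":
        payload = {
            "disease_id": getattr(network, "disease_id", ""),
            "edges": _edges_frame(network).to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    else:
        raise UsageError(f"unknown network format {fmt!r}")


def read_network(path, disease_id: str = ""):
    """Read an edge_tsv network written by :func:`write_network`."""
    from .core import DimeNetwork, Edge  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing network column(s) {missing} in {path}")
    edges = []
    for row in df.itertuples(index=False):
        drugs = getattr(row, "drugs")
        edges.append(
            Edge(
                cell=getattr(row, "cell"),
                gene=getattr(row, "gene"),
                cluster_rank=int(getattr(row, "cluster_rank")),
                dac_score=float(getattr(row, "dac_score")),
                dag_score=float(getattr(row, "dag_score")),
                median_expression=float(getattr(row, "median_expression")),
                druggable=_parse_approved(getattr(row, "druggable"), path),
                drugs=tuple(drugs.split(";")) if isinstance(drugs, str) and drugs else (),
            )
        )
    return DimeNetwork(disease_id=disease_id, edges=edges)
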