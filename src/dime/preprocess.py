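"""From raw counts to the reference cell-type expression matrix, plus the
disease-gene filters applied before any factorization.

The pipeline mirrors standard bulk RNA-seq practice: drop genes with fewer
than 20 reads in 95% of samples, normalise to counts-per-million, take
log2(CPM+1), and collapse replicate samples to the per-cell-type median.
Disease gene sets are stripped of HLA genes (to avoid the myeloid/B-cell
bias of antigen-presentation machinery) and intersected with the genes
actually present in the expression reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DimeError, FormatError
from .io import Disease, DiseaseGeneNetwork, ImmunomeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "read_count_matrix",
    "filter_low_count_genes",
    "cpm_log_transform",
    "aggregate_median_by_celltype",
    "counts_to_immunome",
    "remove_hla_genes",
    "restrict_to_immunome",
]


@dataclass
class CountMatrix:
    """Raw gene x sample read counts plus a sample -> cell-type labelling."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_to_celltype: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("count matrix shape does not match identifiers")
        if (self.counts < 0).any():
            raise FormatError("negative read count")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise FormatError("non-integer read count")
        missing = [s for s in self.sample_ids if s not in self.sample_to_celltype]
        if missing:
            raise FormatError(f"sample(s) without cell-type label: {missing}")

    @property
    def celltypes(self) -> list[str]:
        """Cell types in order of first appearance among samples."""
        seen: list[str] = []
        for s in self.sample_ids:
            ct = self.sample_to_celltype[s]
            if ct not in seen:
                seen.append(ct)
        return seen


def read_count_matrix(counts_path, labels_path) -> CountMatrix:
    """Read a gene x sample count TSV plus a two-column (sample, cell_type)
    label TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0, header=0)
    labels = pd.read_csv(labels_path, sep="\t", header=0, dtype=str)
    if labels.shape[1] < 2:
        raise FormatError(f"label table {labels_path} needs (sample, cell_type) columns")
    mapping = dict(zip(labels.iloc[:, 0], labels.iloc[:, 1]))
    return CountMatrix(
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        df.to_numpy(dtype=float),
        mapping,
    )


def filter_low_count_genes(
    cm: CountMatrix, min_count: int = 20, sample_fraction: float = 0.95
) -> CountMatrix:
    """Remove genes poorly covered across the cohort.

    A gene is removed iff the fraction of samples in which its count is
    below ``min_count`` is at least ``sample_fraction``. Retained genes keep
    their original order.
    """
    if not (0 < sample_fraction <= 1):
        raise DimeError("sample_fraction must be in (0, 1]")
    if min_count < 0:
        raise DimeError("min_count must be >= 0")
    low_frac = (cm.counts < min_count).mean(axis=1)
    keep = low_frac < sample_fraction
    if not keep.any():
        raise DimeError(
            "no genes survive the low-count filter; lower min_count or sample_fraction"
        )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("low-count filter removed %d of %d genes", n_removed, len(keep))
    return replace(
        cm,
        gene_ids=[g for g, k in zip(cm.gene_ids, keep) if k],
        counts=cm.counts[keep],
    )


def cpm_log_transform(cm: CountMatrix) -> np.ndarray:
    """log2(CPM + 1) per entry; CPM = count / library size x 1e6."""
    counts = cm.counts.astype(float)
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise DimeError(f"zero library size for sample {cm.sample_ids[zero[0]]!r}")
    cpm = counts / libsize * 1e6
    return np.log2(cpm + 1.0)


def aggregate_median_by_celltype(
    expr: np.ndarray,
    gene_ids: list[str],
    sample_ids: list[str],
    sample_to_celltype: dict[str, str],
) -> ImmunomeMatrix:
    """Collapse samples to one column per cell type using the per-gene median
    (even sample counts use the midpoint of the two central values)."""
    missing = [s for s in sample_ids if s not in sample_to_celltype]
    if missing:
        raise FormatError(f"unlabelled sample(s): {missing}")
    order: list[str] = []
    for s in sample_ids:
        ct = sample_to_celltype[s]
        if ct not in order:
            order.append(ct)
    cols = []
    for ct in order:
        idx = [i for i, s in enumerate(sample_ids) if sample_to_celltype[s] == ct]
        cols.append(np.median(expr[:, idx], axis=1))
    return ImmunomeMatrix(list(gene_ids), order, np.column_stack(cols))


def counts_to_immunome(
    cm: CountMatrix, min_count: int = 20, sample_fraction: float = 0.95
) -> ImmunomeMatrix:
    """Full preprocessing chain: low-count filter -> log2(CPM+1) -> per-cell-type
    median."""
    filtered = filter_low_count_genes(cm, min_count=min_count, sample_fraction=sample_fraction)
    expr = cpm_log_transform(filtered)
    return aggregate_median_by_celltype(
        expr, filtered.gene_ids, filtered.sample_ids, filtered.sample_to_celltype
    )


def remove_hla_genes(
    net: DiseaseGeneNetwork, exclusion_list: set[str] | None = None
) -> DiseaseGeneNetwork:
    """Drop HLA genes (symbol prefix ``HLA-``, case-insensitive) from every
    disease. ``exclusion_list`` adds explicit extra symbols to remove."""
    extra = exclusion_list or set()

    def is_hla(g: str) -> bool:
        return g.upper().startswith("HLA-") or g in extra

    out = DiseaseGeneNetwork()
    for did, d in net.diseases.items():
        genes = {g for g in d.genes if not is_hla(g)}
        scores = None
        if d.scores is not None:
            scores = {g: s for g, s in d.scores.items() if g in genes}
        out.diseases[did] = Disease(did, d.name, genes, scores)
    return out


def restrict_to_immunome(
    net: DiseaseGeneNetwork, imm: ImmunomeMatrix
) -> DiseaseGeneNetwork:
    """Intersect every disease gene set with the genes present in the
    expression reference; diseases left empty are dropped with a warning."""
    universe = set(imm.gene_ids)
    out = DiseaseGeneNetwork()
    for did, d in net.diseases.items():
        genes = d.genes & universe
        dropped = len(d.genes) - len(genes)
        if dropped:
            logger.info("disease %s: %d gene(s) absent from the immunome", did, dropped)
        if not genes:
            logger.warning("disease %s dropped: no genes in the immunome", did)
            continue
        scores = None
        if d.scores is not None:
            scores = {g: s for g, s in d.scores.items() if g in genes}
        out.diseases[did] = Disease(did, d.name, genes, scores)
    if not out.diseases and net.diseases:
        raise DimeError("no disease retains any immunome gene")
    return out
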