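"""Synthetic immunome generator with planted, known structure.

The generator emulates the salient feature of an immune cell-type expression
reference: genes are cell-type specific. It plants (a) a small number of
large coherent modules — blocks of genes highly expressed in a block of
cell types, the structure NMF is expected to recover — and (b) a sea of
scattered marker genes, each moderately expressed in only one to three
random cell types, which plays the role of realistic cell-specific
background rather than flat noise. Expression values live on the
log2(CPM+1) scale; every entry is truncated-normal (at zero).

Disease gene sets are unions of planted module gene sets plus background
genes, so module recovery, overlap structure and druggability can all be
checked against emitted ground truth.

Default scales match the benchmark conditions used throughout the test
suite: 40 cell types, 300 genes, two disjoint 50-gene x 10-cell modules
with high means 7.0 and 6.0 over a background mean of 1.0 and sd 0.5 (a
high/low gap of 6 for the primary module; the second module sits one unit
lower so the rank-1 "top cluster" is identifiable rather than a coin flip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimeError
from .io import Disease, DiseaseGeneNetwork, DrugGeneNetwork, DrugRecord, ImmunomeMatrix
from .preprocess import CountMatrix

__all__ = [
    "Module",
    "PlantedSpec",
    "GroundTruth",
    "generate_immunome",
    "generate_counts",
    "generate_disease_networks",
    "generate_drug_table",
    "default_spec",
    "benchmark_instance",
    "comparison_instance",
]


@dataclass(frozen=True)
class Module:
    """A planted block: ``genes`` highly expressed (mean ``mean``) in
    ``cells``."""

    name: str
    genes: tuple[str, ...]
    cells: tuple[str, ...]
    mean: float


@dataclass
class PlantedSpec:
    n_cells: int = 40
    n_genes: int = 300
    modules: list[Module] = field(default_factory=list)
    low_mean: float = 1.0
    sd: float = 0.5
    scatter_background: bool = True
    scatter_mean: float = 4.0
    scatter_max_cells: int = 3
    library_size: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if m.mean <= self.low_mean:
                raise DimeError(f"module {m.name}: mean must exceed low_mean")
            if seen & set(m.genes):
                raise DimeError(f"module {m.name}: overlapping gene sets")
            seen |= set(m.genes)

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def cell_ids(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_cells)]


@dataclass
class GroundTruth:
    """Planted memberships emitted alongside every generated matrix."""

    modules: dict[str, Module]
    background_genes: tuple[str, ...]
    background_cells: tuple[str, ...]

    def module_genes(self, name: str) -> set[str]:
        return set(self.modules[name].genes)

    def module_cells(self, name: str) -> set[str]:
        return set(self.modules[name].cells)


def _mean_matrix(spec: PlantedSpec, rng: np.random.Generator) -> np.ndarray:
    genes = spec.gene_ids()
    cells = spec.cell_ids()
    gidx = {g: i for i, g in enumerate(genes)}
    cidx = {c: j for j, c in enumerate(cells)}
    mu = np.full((spec.n_genes, spec.n_cells), spec.low_mean)
    module_genes: set[str] = set()
    for m in spec.modules:
        module_genes |= set(m.genes)
        rows = [gidx[g] for g in m.genes]
        cols = [cidx[c] for c in m.cells]
        mu[np.ix_(rows, cols)] = m.mean
    if spec.scatter_background:
        # every non-module gene becomes a marker of a few random cell types
        for g in genes:
            if g in module_genes:
                continue
            n_marked = int(rng.integers(1, spec.scatter_max_cells + 1))
            marked = rng.choice(spec.n_cells, size=n_marked, replace=False)
            mu[gidx[g], marked] = spec.scatter_mean
    return mu


def generate_immunome(spec: PlantedSpec) -> tuple[ImmunomeMatrix, GroundTruth]:
    """Truncated-normal expression around the planted mean structure;
    deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    mu = _mean_matrix(spec, rng)
    values = np.maximum(rng.normal(mu, spec.sd), 0.0)
    imm = ImmunomeMatrix(spec.gene_ids(), spec.cell_ids(), values)
    module_genes = {g for m in spec.modules for g in m.genes}
    module_cells = {c for m in spec.modules for c in m.cells}
    gt = GroundTruth(
        modules={m.name: m for m in spec.modules},
        background_genes=tuple(g for g in spec.gene_ids() if g not in module_genes),
        background_cells=tuple(c for c in spec.cell_ids() if c not in module_cells),
    )
    return imm, gt


def generate_counts(
    spec: PlantedSpec, samples_per_celltype: int = 3
) -> tuple[CountMatrix, GroundTruth]:
    """Count-level variant (to exercise preprocessing): Poisson counts with
    rates proportional to the planted CPM-scale means, renormalised to the
    library size. Relative planted structure (module vs background contrast)
    is preserved; absolute log2(CPM+1) levels shift with the renormalisation."""
    rng = np.random.default_rng(spec.seed)
    mu = _mean_matrix(spec, rng)
    cpm = np.power(2.0, mu) - 1.0
    rate = cpm / cpm.sum(axis=0, keepdims=True) * spec.library_size
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    cols = []
    for j, cell in enumerate(spec.cell_ids()):
        for r in range(samples_per_celltype):
            sid = f"{cell}_s{r}"
            sample_ids.append(sid)
            labels[sid] = cell
            cols.append(rng.poisson(rate[:, j]))
    cm = CountMatrix(spec.gene_ids(), sample_ids, np.column_stack(cols), labels)
    module_genes = {g for m in spec.modules for g in m.genes}
    module_cells = {c for m in spec.modules for c in m.cells}
    gt = GroundTruth(
        modules={m.name: m for m in spec.modules},
        background_genes=tuple(g for g in spec.gene_ids() if g not in module_genes),
        background_cells=tuple(c for c in spec.cell_ids() if c not in module_cells),
    )
    return cm, gt


def generate_disease_networks(
    ground_truth: GroundTruth,
    assignments: dict[str, list[str]],
    n_background_genes: int = 100,
    seed: int = 0,
    disjoint_background: bool = True,
    names: dict[str, str] | None = None,
) -> DiseaseGeneNetwork:
    """Each disease = union of its assigned modules' genes plus random
    background genes. With ``disjoint_background`` the background pools of
    different diseases never overlap, so diseases sharing no module share no
    genes at all."""
    rng = np.random.default_rng(seed)
    pool = list(ground_truth.background_genes)
    rng.shuffle(pool)
    net = DiseaseGeneNetwork()
    offset = 0
    for did in sorted(assignments):
        mods = assignments[did]
        genes: set[str] = set()
        for m in mods:
            genes |= ground_truth.module_genes(m)
        if n_background_genes:
            if disjoint_background:
                take = pool[offset : offset + n_background_genes]
                if len(take) < n_background_genes:
                    raise DimeError("background gene pool exhausted")
                offset += n_background_genes
            else:
                take = list(rng.choice(pool, size=n_background_genes, replace=False))
            genes |= set(take)
        name = (names or {}).get(did, did)
        net.diseases[did] = Disease(did, name, genes)
    return net


def generate_drug_table(
    ground_truth: GroundTruth,
    druggable_fraction: float = 0.2,
    seed: int = 0,
    source: str = "custom",
    approved: bool = True,
) -> DrugGeneNetwork:
    """Flag a seeded random subset of planted-module genes as druggable with
    synthetic drug names."""
    if not (0 <= druggable_fraction <= 1):
        raise DimeError("druggable_fraction must be in [0, 1]")
    genes = sorted({g for m in ground_truth.modules.values() for g in m.genes})
    rng = np.random.default_rng(seed)
    n_take = int(round(druggable_fraction * len(genes)))
    chosen = sorted(rng.choice(len(genes), size=n_take, replace=False))
    dgn = DrugGeneNetwork()
    for i in chosen:
        g = genes[i]
        dgn.add(g, DrugRecord(f"drug_{g}", source, approved))
    return dgn


# ---------------------------------------------------------------------------
# canonical benchmark instances


def default_spec(seed: int = 0, n_modules: int = 2) -> PlantedSpec:
    """The canonical 40-cell, 300-gene immunome with planted modules.

    Module i occupies 50 genes x 10 cells at mean 7.0 - i (i = 0 is the
    strongest); supports up to 4 modules (40 cells).
    """
    if not (1 <= n_modules <= 4):
        raise DimeError("n_modules must be 1..4")
    genes = [f"G{i:04d}" for i in range(300)]
    cells = [f"C{i:02d}" for i in range(40)]
    modules = [
        Module(
            name=f"M{i + 1}",
            genes=tuple(genes[50 * i : 50 * (i + 1)]),
            cells=tuple(cells[10 * i : 10 * (i + 1)]),
            mean=7.0 - i,
        )
        for i in range(n_modules)
    ]
    return PlantedSpec(n_cells=40, n_genes=300, modules=modules, seed=seed)


def benchmark_instance(seed: int = 0):
    """Two-module planted benchmark: immunome, ground truth, and a single
    disease 'D1' = M1 u M2 genes + 100 background genes (each module is 25%
    of the disease matrix rows; each module's cells 25% of columns)."""
    imm, gt = generate_immunome(default_spec(seed=seed, n_modules=2))
    net = generate_disease_networks(
        gt, {"D1": ["M1", "M2"]}, n_background_genes=100, seed=seed + 1
    )
    return imm, gt, net


def comparison_instance(seed: int = 0):
    """Three diseases for overlap analysis: D1 = M1 u M2, D2 = M1 u M3
    (sharing module M1 with D1), D3 = M4 only — unrelated, with disjoint
    background pools, so D3 shares no gene with D1 or D2."""
    imm, gt = generate_immunome(default_spec(seed=seed, n_modules=4))
    net = generate_disease_networks(
        gt,
        {"D1": ["M1", "M2"], "D2": ["M1", "M3"], "D3": ["M4"]},
        n_background_genes=30,
        seed=seed + 1,
        disjoint_background=True,
    )
    return imm, gt, net
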