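# dime

**Disease-gene IMmune cell Expression (DIME)** — map disease-associated gene
sets onto an immune cell-type expression reference to identify the cell types
(DACs, disease-associated cells) and genes (DAGs, disease-associated genes)
that drive a disease, compare diseases through the cell–gene mechanisms they
share, and overlay drug–gene interactions to nominate repurposing candidates.

The package is aimed at computational immunologists working with curated
disease–gene associations (e.g. a DisGeNet download or a custom gene list)
and a bulk RNA-seq reference of sorted immune cell types ("immunome"). All
inputs are plain TSV; a synthetic-data module generates fully specified
planted benchmarks so every stage can be exercised and validated without any
external download.

## Method

For a disease *D* with gene set *G\_D*, the immunome (genes × cell types,
log2(CPM+1), per-cell-type median) is restricted to *G\_D*, giving the
disease expression matrix *X\_D*. KL-divergence non-negative matrix
factorization with multiplicative updates factors

&nbsp;&nbsp;&nbsp;&nbsp;*X\_D* ≈ *W H* = Σᵢ *wᵢ hᵢ*,&nbsp;&nbsp;*i* = 1…*k*,

where column *wᵢ* weights the genes of cluster *i* and row *hᵢ* its cell
types. The model order *k* is chosen by consensus clustering over random
restarts, scored by the cophenetic correlation coefficient. Within each
cluster, DAC scores are *hᵢ*/max(*hᵢ*) and DAG scores *wᵢ*/max(*wᵢ*);
members at or above the 75th percentile of their cluster's scores are the
**top DACs/DAGs**. Clusters are ranked by ‖*wᵢ hᵢ*‖_F = ‖*wᵢ*‖₂‖*hᵢ*‖₂; the
rank-1 "top cluster" is the component that captures most of *X\_D*. The
bipartite union of top DAC × top DAG pairs over all clusters is the DIME
network of the disease.

Downstream analyses:

- **Jackknife consistency** — rerun the analysis on random 70% subsamples of
  genes (or cell types), count how often each item recurs among the top
  cluster's top members, and test the Pearson correlation of counts against
  the original scores.
- **Common cell–gene networks** — intersect two diseases' DIME networks on
  (cell, gene) pairs; score overlap by Jaccard index and a one-sided Fisher
  exact (hypergeometric) test.
- **Drug repurposing** — druggable genes inside statistically significant
  common networks, flagged when they are top DAGs of the rank-1 cluster in
  every disease involved.

## Worked example

`examples/01_planted_benchmark.py` generates a 300-gene × 40-cell-type
synthetic immunome with two planted modules and runs the full analysis:

```
selected k = 2  (cophenetic profile: k=2: 1.000, k=3: 1.000, k=4: 0.985, k=5: 0.979, k=6: 0.977)

cluster rank 1  (Frobenius weight 157.8)
  top DACs (10): C00, C01, C02, C03, C04, C05, C06, C07, C08, C09
  top DAGs: 50 genes

cluster rank 2  (Frobenius weight 134.0)
  top DACs (10): C10, C11, C12, C13, C14, C15, C16, C17, C18, C19
  top DAGs: 50 genes

planted top-module cells recovered: 10/10
```

The consensus procedure selects the planted model order (k = 2), the rank-1
cluster is the stronger planted module (cells C00–C09 at expression mean 7),
and its top DACs/DAGs coincide exactly with the planted membership.
`examples/03_compare_diseases.py` then compares three diseases, two of which
share a planted module:

```
disease_a disease_b       item_kind  overlap  jaccard      fisher_p significance
       D1        D2 cell_gene_pairs      280  0.20438 1.655361e-134          ***
       D1        D3 cell_gene_pairs        0  0.00000  1.000000e+00
       D2        D3 cell_gene_pairs        0  0.00000  1.000000e+00
```

The shared-module pair shows a large, vanishing-p overlap; unrelated pairs
share nothing. The remaining examples cover count preprocessing, jackknife
stability and the drug-repurposing overlay.

A thin CLI wraps the same library calls
(`dime simulate|preprocess|dime|compare|jackknife|drugs|all`); run
`dime --help` for the flags.

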