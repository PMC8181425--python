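# Methods

## Model and procedure

DIME treats a disease as a set of associated genes and asks which immune
cell types express that gene set coherently. The reference ("immunome") is a
genes × cell-types matrix of log2(CPM+1) values, one column per cell type
(median over replicate samples). For disease *D*, the rows belonging to its
gene set form the disease matrix *X_D*, which is factored as *X_D ≈ WH* with
*W, H ≥ 0* by minimising the generalized Kullback–Leibler divergence

    D(X ‖ WH) = Σ_ij [ X_ij log(X_ij/(WH)_ij) − X_ij + (WH)_ij ],   0·log 0 ≡ 0,

with the classical multiplicative updates

    H_aj ← H_aj · Σ_i W_ia X_ij/(WH)_ij / Σ_i W_ia
    W_ia ← W_ia · Σ_j H_aj X_ij/(WH)_ij / Σ_j H_aj

which never increase the divergence. Each cluster *i* contributes a rank-1
part *w_i h_i*; gene weights *w_i* and cell weights *h_i* are max-scaled to
[0, 1] to give DAG and DAC scores, membership is score ≥ the 75th percentile
of the cluster's score multiset (linear interpolation between order
statistics), and clusters are ranked by ‖w_i h_i‖_F = ‖w_i‖₂‖h_i‖₂ (ties
keep the lower cluster index). The factorization that is scored is the best
(lowest final divergence) of `n_restarts` seeded runs, so reported scores
come from a single factorization.

### Model-order selection

For each candidate *k*, `n_runs_consensus` randomly restarted factorizations
are reduced to binary cell-connectivity matrices (columns clustered by
argmax over H; ties to the lowest cluster index) and averaged into a
consensus matrix. Stability is the cophenetic correlation between the
consensus distances (1 − consensus) and the cophenetic distances of their
average-linkage dendrogram; a constant distance vector (perfect consensus)
is defined as 1. The selected *k* is the smallest one attaining the maximum
coefficient, where coefficients within 1e-7 of the maximum count as tied —
correlations that close are numerically indistinguishable, and without the
tolerance the choice between candidate orders that are all perfectly stable
would be decided by floating-point noise. The "maximum with smallest-k
tie-break" rule, the restart counts and the k range (default 2–7, capped at
min(dims)−1) are configuration, since reasonable alternatives exist
("first fall" rules, other ranges); all are recorded in the run summary.

### Numerical choices

- Entries of W, H are floored at ε = 1e-12; (WH) is floored at ε inside
  logs and divisions. Convergence: relative divergence change < 1e-6 over a
  10-iteration window, cap 2000 iterations.
- Consensus restarts only feed connectivity (an argmax pattern that
  stabilises long before convergence), so they run under a tighter cap
  (`consensus_max_iter` = 300) than the scored factorization.
- The divergence trace is recorded every iteration and asserted
  non-increasing (tolerance 1e-9) in tests.
- Restart seeds are `seed + i`; per-k consensus seeds are offset by a prime
  stride (7919·k) so candidate orders do not share restart streams.
- Degenerate inputs: all-zero rows/columns of *X_D* are rejected with the
  offending index; all-zero score vectors are an error (a cluster carrying
  no weight); two empty sets have no Jaccard index.

## Preprocessing

Counts → expression follows standard bulk RNA-seq practice: a gene is
removed iff its count is below 20 in ≥ 95% of samples (the boundary is
taken as ≥, and both numbers are parameters); CPM = count/library·10⁶;
expression = log2(CPM+1); cell-type profiles are per-gene medians (even
counts: midpoint). Disease gene sets are stripped of HLA genes by the
case-insensitive symbol prefix `HLA-` — prefix matching is the reproducible
reading of "HLA-associated", and an explicit exclusion list can extend it —
then intersected with the immunome's genes (dropped counts are logged;
symbols are opaque and case-sensitive, no alias mapping).

## Statistics

- **Overlap**: Jaccard index on (cell, gene) edge sets (or gene sets), and a
  one-sided enrichment Fisher exact test, P(X ≥ overlap) for
  X ~ Hypergeom(N, |A|, |B|). The universe N is explicit and configurable:
  for edge comparisons the default is |cells| × |union of loaded disease
  genes|; for gene comparisons, all genes in the loaded network. One-sided
  enrichment is the natural test for "how confident is this overlap";
  p-values are reported raw (stars at 0.05/0.01/0.001) with the universe in
  every output row so users can correct for multiplicity downstream.
- **Jackknife**: each simulation draws ⌊frac·n⌋ items without replacement
  (default frac = 0.70, 1000 simulations; the benchmarks here use 200) and
  reruns the full analysis with k reselected — the conservative reading of
  "rerun the method". Gene-mode simulations count the top cluster's top
  DACs; cell-mode simulations count its top 10 DAGs by score (the tracked
  sets mirror the method's asymmetric protocol). The per-simulation seed
  drives only the subsample draw; the inner run keeps the caller's seed, so
  frac = 1.0 degenerates exactly to the original run. Consistency is the
  two-sided Pearson correlation (t-distribution, n−2 df) between original
  scores and occurrence counts, significant at p ≤ 0.05; zero-variance
  vectors make the correlation undefined and the result is flagged
  insignificant with a warning.

## Drug overlay

Druggability annotation is pure decoration (edges and scores unchanged).
Repurposing candidates are druggable genes appearing in significant
(p ≤ alpha) common networks; `top_cluster_target` is true when the gene is a
top DAG of the rank-1 cluster in *every* disease it is listed for — both the
permissive (any cluster) and strict tiers are visible rather than choosing
silently. "Approved" is an input flag on drug records, not a live lookup.

## Synthetic benchmarks

The generator emulates the one property of an immune expression reference
the method depends on: genes are cell-type specific. A planted instance has

- 40 cell types × 300 genes (the reference scale of a sorted-cell immunome);
- planted modules of 50 genes × 10 cells: blocks at high mean expression,
  the structure the factorization should recover. The default benchmark
  plants two disjoint modules at means 7.0 and 6.0 (log2(CPM+1) scale,
  typical marker-gene levels) over a background mean of 1.0, sd 0.5,
  truncated at zero — a high/low gap of 6 for the primary module. The
  second module sits one unit lower so the rank-1 cluster is identifiable;
  with exactly symmetric modules the "top cluster" would be a coin flip and
  the jackknife occurrence statistic would have no stable target.
- scattered background: every non-module gene is a marker of 1–3 random
  cell types at mean 4.0. Flat uniform background would itself be a
  coherent rank-1 component and would distort model-order selection; a
  scatter of micro-markers behaves like unstructured variation, which is
  also the more realistic picture.
- the benchmark disease = both modules' genes + 100 background genes, so
  each module is 25% of the disease matrix rows and each module's cells 25%
  of the columns — sized so the top-25th-percentile membership rule can in
  principle recover planted membership exactly.

The comparison instance plants four modules and three diseases: D1 = M1∪M2,
D2 = M1∪M3 (sharing M1), D3 = M4, with disjoint per-disease background
pools, so the unrelated pairs share no genes at all. A count-mode generator
(Poisson, rates proportional to the planted CPM-scale means) exercises the
preprocessing chain; renormalisation to the library size shifts absolute
levels while preserving the planted contrasts.

What passing these benchmarks shows — and does not. The planted instances
have well-separated, noise-perturbed block structure; recovering them
demonstrates the correctness of the factorization, selection, ranking,
stability and overlap machinery, not that real immunome data contain such
clean modules. Real references add correlated lineages, batch structure and
heavy-tailed expression that the generator deliberately omits.

## Problem sizes and configurations used in tests

The library defaults are 30 restarts for both the scored factorization and
each consensus, k range 2–7, 1000 jackknife simulations. The test and
benchmark scripts use lighter settings that leave the recovered structure
unchanged on the planted instances: 10 restarts over k 2–6 for recovery
benchmarks, 8 consensus restarts over k 2–4 with best-of-3 fits inside the
jackknife, and 200 simulations.

## Known limitations

- NMF multiplicative updates converge to local optima; best-of-restarts
  mitigates but does not guarantee the global optimum.
- A gene or cell may be a top member of several clusters; displays that
  assume exclusive membership should use the per-edge cluster rank.
- The Fisher universe for edge overlaps is a modelling choice; absolute
  p-values move with it (the Jaccard index does not).
- Gene identifiers are never mapped across vocabularies; mismatched symbol
  conventions between inputs silently shrink intersections (dropped counts
  are logged for exactly this reason).
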