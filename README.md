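# coexnet

Weighted gene co-expression network analysis with module detection by
**modularity / modularity-density maximization**, permutation-based
significance testing, and Rand-index partition comparison.

## The problem

RNA-seq differential-expression analysis yields long gene lists but no
picture of how those genes act together. Co-expression network analysis
addresses this: genes are nodes, edges reflect correlated expression across
samples, and densely interconnected **modules** often correspond to shared
pathways. The standard weighted-correlation workflow detects modules by
hierarchical clustering with a dendrogram cut, which requires user-set
parameters (minimum cluster size, split sensitivity) and tends to leave
many genes unassigned. `coexnet` replaces that step with community
detection by quality-function maximization, which needs no such
parameters: module number and sizes come out of the optimization, and the
only genes left unassigned are those isolated by the edge threshold.

## The model

Given an expression matrix `X = [x_ij]` (n genes × m samples):

1. **Feature selection.** Per-timepoint DE tables are combined, keeping
   for each gene the row with the lowest FDR; the list is filtered to
   FDR ≤ 10⁻⁵ and fold change ≥ 1.5 (|log₂FC| ≥ 0.59).
2. **Soft-threshold adjacency.** `a_ij = |r_ij|^β` where `r_ij` is the
   Pearson correlation of genes i and j. β is the smallest integer power
   whose connectivity distribution fits a scale-free topology at R² ≥ 0.9
   (log–log regression of the connectivity histogram), or can be fixed.
3. **Hard edge threshold.** Edges are kept where |r_ij| ≥ 0.7; genes with
   no surviving edge remain as isolated nodes and end up *unassigned*.
4. **Module detection.** Maximization of either weighted Newman modularity

       Q = Σ_c [ W_c^in / W − (S_c / 2W)² ]

   or modularity density `Qds`, which weights each community's
   contribution by its internal density `d_c = 2W_c^in / (n_c(n_c−1))` and
   adds a split penalty between community pairs, counteracting the
   resolution limit of plain Q. Optimization is greedy agglomeration plus
   Kernighan–Lin-style fine-tuning; components of ≤ 8 nodes are solved
   exactly by enumeration.
5. **Significance.** The observed (maximized) modularity is compared with
   the distribution over networks rewired uniformly while conserving the
   edge count and the multiset of edge weights (re-clustered each time),
   summarized as a z-score. A degree-preserving null is available.
6. **Evaluation.** Partitions are compared by the Rand index, treating
   every unassigned gene as a cluster by itself; an FDR-sweep reruns the
   pipeline over a grid of cutoffs and selects the one maximizing the
   median module size.

A synthetic-data module generates planted-module expression matrices
(latent-factor blocks with controlled within-module correlation) and
negative-binomial count data with condition × timepoint effects, so every
stage can be exercised without external data.

## Worked example

```sh
coexnet simulate bundle --seed 11 -o inputs
coexnet pipeline inputs/expression.tsv inputs/de_*.tsv \
    --permutations 200 --seed 11 -o run
coexnet compare run/partition.tsv inputs/truth_partition.tsv
```

prints

```
bundle with 140 genes -> inputs
110 genes selected; 5 modules, 10 unassigned; Q = 0.800
permutation z = 105.1
RI = 1.000 (5995/5995 pairs agree; unassigned: 10 vs 10)
```

The bundle plants five 20-gene modules (within-module correlation 0.95,
30 samples) plus 10 significant-but-uncorrelated genes and 30 genes that
fail the FDR ≤ 10⁻⁵ cutoff. Selection keeps the 110 network genes; the
five modules are recovered exactly (Rand index 1.0 against the planted
truth), the 10 uncorrelated genes isolate and are reported unassigned, and
the observed modularity Q = 0.800 sits about 105 standard deviations above
the rewiring null — strong evidence of non-random modular structure.
`run/clustering.json` additionally records Qds = 0.696, the auto-selected
power β = 4 and its scale-free fit R² = 0.99.

Every stage is also runnable standalone (`select-features`,
`build-network`, `cluster`, `significance`, `compare`, `sweep`,
`simulate`); see `coexnet --help`.

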