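# Methods

This note records the models implemented in `coexnet`, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic benchmarks do and do not demonstrate.

## Feature selection

Per-comparison DE tables (`gene_id, log2_fc, p_value, fdr`) are merged
into one record per gene, keeping the row with the lowest FDR across
comparisons. Ties on FDR are broken by larger |log₂FC|, then by
lexicographically smaller comparison label — the ordering is arbitrary but
must be deterministic so repeated runs byte-match. The fold-change filter
is symmetric: fold change ≥ 1.5 is applied as |log₂FC| ≥ 0.59 to both
directions. Defaults: `fdr_max = 1e-5` for the network stage (the
conventional per-comparison DE extraction uses 0.05), `min_abs_log2fc =
0.59`. DE testing itself is upstream of this package; the bundled
approximate test (below) exists only for synthetic end-to-end runs.

## Network construction

The adjacency is the unsigned weighted-correlation form
`a_ij = |r_ij|^β` with a zero diagonal, so connectivity
`k_i = Σ_j a_ij` excludes self-pairs. The hard edge filter keeps pairs
with |r_ij| ≥ `min_abs_corr` (default 0.7). The absolute-value convention
is used in both places because the power function on |r| defines an
unsigned network; a `signed=True` option filters on signed correlation
instead for users who want anti-correlated genes separated.

The scale-free criterion bins connectivity into `n_bins = 10` equal-width
bins, drops empty bins, and regresses log₁₀(bin frequency) on log₁₀(mean
connectivity per bin); R² of that line is the fit statistic and the slope
is reported (negative for scale-free-like topologies). Frequency rather
than density is used on the y-axis; with equal-width bins the two differ
only by a constant and leave R² unchanged. R² is reported as the plain
coefficient of determination, not signed by the slope; β selection
requires at least 3 non-empty bins and raises a degenerate-fit error when
all connectivities coincide. `pick_soft_threshold` scans β ∈ {1..20} and
returns the smallest power reaching the target R² (default 0.9); if none
qualifies it returns the best-fitting power flagged `target_met=False`
rather than failing — a weak scale-free fit is a property of the data, not
an error. Note that block-structured planted-module data is not scale-free
by construction, so on synthetic benchmarks the flag is often the
informative output.

## Module detection

Two quality functions are supported on the thresholded weighted graph.
Weighted Newman modularity:

    Q = Σ_c [ W_c^in / W − (S_c / 2W)² ]

with `W` the total edge weight, `W_c^in` the internal weight and `S_c`
the summed node strength of community c. Modularity density:

    Qds = Σ_c [ (W_c^in / W)·d_c − ((2W_c^in + W_c^out) / 2W · d_c)² ]
          − Σ_{c<c'} W_cc'² / (W · n_c · n_c')

with internal density `d_c = 2W_c^in / (n_c(n_c−1))`, defined as 0 for
singletons (the n_c = 1 denominator is otherwise zero), and the last term
the pairwise split penalty written in its unordered form. Edge weights are
the soft adjacency values, not raw correlations: clustering operates on
the weighted, thresholded adjacency matrix. Both Q and Qds of the final
partition are always reported regardless of which was optimized; the
optimizer defaults to Qds, whose density weighting resists the resolution
limit.

Optimization proceeds in three deterministic phases on a dense
community-aggregate representation (community sizes, internal weights,
strengths, and the inter-community weight matrix, with all pair gains
evaluated as vectorized local deltas):

1. greedy agglomeration — every non-isolated node starts as a singleton
   and the connected community pair with the largest positive gain is
   merged until no merge helps;
2. improving sweeps — single-node moves to neighbouring communities or to
   a fresh singleton (a split proposal), applied when they raise the
   objective by more than the convergence tolerance (1e-12);
3. Kernighan–Lin refinement — a chain of locked best single moves applied
   even at negative gain, rolled back to the best prefix; this escapes
   local optima that need several coordinated moves.

Phases 2–3 and renewed merges iterate to a joint local optimum. Ties are
broken by the smallest community-index pair and nodes are processed in
sorted order, so results are reproducible; the seed only drives optional
randomized restarts (`restarts > 1` shuffles the sweep order and keeps the
best final objective). Connected components of at most 8 nodes are solved
exactly by enumerating all set partitions (Bell(8) = 4140), which is both
cheaper than the heuristic at that size and provably optimal.

Unassigned genes are exactly the nodes isolated by the edge threshold —
the only mechanism in this workflow that leaves a gene outside every
module; they are excluded from optimization and labelled 0.
`finalize_partition` additionally dissolves modules below a configurable
`min_module_size` (default 1 = no effect) and relabels modules 1..K by
decreasing size so equivalent partitions serialize identically. When
scored by Q or Qds, unassigned genes count as their own singleton
communities.

## Permutation significance

The null model follows the conservation-of-links description literally:
each permutation places the same number of edges, carrying the same
multiset of weights, on node pairs drawn uniformly without replacement.
Uniform rewiring does **not** preserve the degree distribution (a network
rewired this way is generally no longer scale-free, whatever the original
topology was); a degree-preserving double-edge-swap null is therefore
exposed as an option (`null_model="degree"`), with weights shuffled over
the swapped topology. On very sparse or rigid graphs the swap routine may
achieve fewer swaps than requested; partial mixing still preserves
degrees and is accepted.

Each permuted network is re-clustered from scratch and the modularity Q of
its optimized partition recorded — the per-network modularity of a
permutation is its maximized value, not the observed partition rescored on
shuffled edges. The significance stage maximizes Q by default even when
the main clustering optimized Qds: the test statistic is modularity, and
on uniformly rewired graphs density structure is typically so weak that a
Qds optimizer retains a single community (Q ≡ 0), collapsing the null
spread. The summary is `z = (Q_obs − mean(Q_null)) / sd(Q_null)`; a
(near-)zero null standard deviation is flagged degenerate with z
undefined rather than raising. Default 1000 permutations; the bundled
benchmarks and the acceptance script use 200, which is ample for a z-score
of this magnitude and keeps a full run around a minute.

## Partition comparison and FDR sweep

The Rand index is computed by pair counting through the contingency
table. Unassigned genes are first converted to singleton clusters within
their own partition (`unassigned_as_singletons=True`, the default):
unassigned genes are not similar to each other and must not be scored as
one large agreeing cluster. The raw RI, not the adjusted form, is the
headline statistic.

The FDR sweep reruns selection → network → clustering over a sorted cutoff
grid and records gene count, module count and median module size per
cutoff; the selected cutoff maximizes the median module size. The median
is taken over assigned modules only — unassigned singletons are not
modules in the pipeline's own output — and module count is recorded
alongside so the alternative reading (number of clusters) is also
reproducible. Cutoffs yielding fewer than 3 genes, or a graph with no
edges, are flagged degenerate and skipped rather than failing the sweep.

## Synthetic data

`generate_modular_expression` plants each module as
`x = sqrt(ρ)·f + sqrt(1−ρ)·ε` with one standard-normal latent factor `f`
per module across samples, giving expected within-module correlation ρ —
the simplest structure in which a module is many genes tracking one
underlying profile (the eigengene picture). Defaults are five modules of
20 genes, ρ = 0.95, 30 samples: strongly separated modules at the sample
size of a two-group, five-timepoint, three-replicate design. Noise genes
are independent normals.

`generate_counts` draws negative-binomial counts (variance μ + φμ², φ =
0.1) with log-normal baseline means (log-mean 4, log-sd 1.5) and
log-normal library factors (log-sd 0.15); a fixed 10% of genes is shifted
by ±2 log₂ units in the treated group at every timepoint, with 3
replicates per group — a persistent exposure effect at desk scale.

`approximate_de_test` is a normal-approximation Wald test on
library-normalized log₂ counts with the per-gene pooled variance squeezed
toward the genome-wide mean (prior df 4, matching the residual df of a
3-vs-3 design) and BH correction. It is deliberately simple and **not**
equivalent to an NB GLM fit: the normal reference is approximate at such
replicate counts, and combining minima across timepoints adds
multiplicity that is not re-corrected, so its realized false-discovery
proportion exceeds the nominal level (roughly 0.2 at 0.05 in the bundled
simulation, at recall near 1). It exists so synthetic end-to-end runs can
produce DE tables of the right shape.

`generate_pipeline_bundle` combines the two views into internally
consistent pipeline inputs: module genes with min-FDR well below 10⁻⁵,
ten significant-but-uncorrelated genes (which should isolate and end
unassigned), and thirty sub-threshold genes (which selection should
drop). What passing these benchmarks shows is that the machinery —
selection, thresholding, optimization, null, comparison — behaves
correctly under its own assumptions. What it does not show: real
co-expression modules are not equicorrelated blocks, real networks carry
overlapping and hierarchical structure, and real DE statistics come from
NB likelihoods; recovery rates on this synthetic design are upper bounds,
not forecasts for experimental data.

## Numerical choices and limitations

* Convergence tolerance 1e-12 on objective improvements; accumulated
  float drift in the aggregate state is bounded by recomputing the full
  objective per restart.
* Correlations are clipped to [−1, 1] after `corrcoef`; constant gene
  rows are rejected up front with the offending gene ids.
* Stage seeds derive from the single run seed with fixed offsets
  (clustering +0, significance +1, sweep +2) so stages are independently
  reproducible.
* The optimizer's dense state is O(n²) memory; comfortable to a few
  thousand network genes, not intended for whole-transcriptome graphs
  (the workflow filters to a few hundred significant genes first).
* Partitions produced by other algorithms (dendrogram cutting,
  indirect-path modularity) are consumed from files for comparison only;
  those algorithms are out of scope here.
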