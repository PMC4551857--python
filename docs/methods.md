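# Methods

`neurocoex` asks whether a labelled set of genes (canonically: genes
annotated to the GO "immune system process" category, here called the IS
set) shows coordinated expression in a tissue beyond what random gene sets
show, and whether that coordination is organized as a clustered network
rather than scattered pairs. All significance statements are resampling- or
permutation-based; no distributional assumption is placed on the expression
values themselves.

## Preprocessing model

The expression substrate is a genes × samples matrix. For array data the
chain is: (1) remove probes whose intensity is strictly below the
per-sample mean of negative-control probes in **every** sample (a probe
exactly equal to the control mean is retained — "lower than" is read
strictly); (2) drop probes mapping to more than one gene and average the
remaining probes per gene; (3) divide each sample column by its total
signal, so columns sum to one. Filtering precedes summarization because the
filter is defined at probe level. Missing values are rejected at load time
rather than imputed: no imputation rule is part of the model, and silently
inventing one would change every downstream rank. Normalization is
idempotent to ~1e-12, and the whole chain is deterministic.

Correlation is computed on the (normalized) values as-is by default. A
`log2` option exists because public RNA-seq summaries are sometimes
log-transformed upstream and the Pearson estimate is not invariant to that
choice; it requires strictly positive values. Genes with zero variance have
undefined correlation: their rows are NaN, they are excluded from medians,
thresholds, and resampling backgrounds, and never silently scored.

## Set-level co-expression statistic

For a set A the statistic is the **median** Pearson correlation over all
|A|(|A|−1)/2 distinct pairs (between two disjoint sets A, B: all |A|·|B|
cross pairs). The median is used rather than the mean because pair
correlations within a structured set are heavy-tailed. The null is obtained
by drawing `n_resamples` (default 10,000) equally sized random gene sets
from the background, uniformly without replacement within a draw,
independently across draws, and recording the same median. The observed
value is summarized as

- Z = (observed − mean(null)) / sd(null), with the sample SD (n−1);
- an add-one empirical p, p = (1 + #{null ≥ observed}) / (1 + n), so a
  Monte Carlo p of exactly zero cannot occur. The upper tail is the
  default; the lower tail is selectable.

The IS and NS sets are made disjoint before any of this (genes annotated to
both are removed from both), so cross-set co-expression cannot be inflated
by shared members.

## Thresholded network and degree-preserving null

Gene pairs with correlation **strictly above** a cutoff R (default 0.9,
signed; an absolute-value mode exists) form a simple undirected graph.
Cliquishness is measured by the Watts–Strogatz local clustering
coefficient, C = 2T/(k(k−1)) for a node of degree k with T edges among its
neighbors. Nodes of degree < 2 have no defined C and are excluded from the
network mean (scoring them 0 would deflate observed and null means alike
while diluting the contrast).

The null ensemble holds the degree sequence fixed exactly: each null
network is produced by double-edge-swap rewiring of the observed graph
(target 10× the edge count of successful swaps, rejecting swaps that would
create self-loops or duplicate edges). Graphs that admit no valid swap
(triangles, complete graphs) are returned unchanged, so a rigid graph
yields ratio 1 and p 1 rather than an error. The degree sequence of every
draw is asserted equal to the observed one. Reported are the ratio
observed C̄ / mean(null C̄) and the add-one upper-tail p. A sweep repeats
this across a threshold grid; thresholds whose graphs are empty (or have no
node of degree ≥ 2) are reported as absent rather than zero.

A caveat found during validation and worth stating: thresholded graphs of
*pure-noise* sample correlations are not configuration-model-like. Because
correlation matrices are positive semi-definite, high r(a,b) and r(a,c)
make a high r(b,c) more likely, so even structureless data keeps a small
intrinsic transitivity (ratios ≈ 1.3–1.5 at thresholds near the sampling
noise scale, reproducibly). Abstract Erdős–Rényi graphs show no such bias
(mean ratio ≈ 1.0 over replicate graphs). Excess-clustering claims should
therefore be read against module-free *correlation* controls, which this
package's shuffle control provides; the planted-module excess (ratios ≈ 2–5)
is far above the artifact.

The edge-composition test asks whether edges incident to the focal set
connect within the set more often than random partner choice predicts:
with f focal nodes among n graph nodes, an incident edge is within-set with
probability (f−1)/(n−1); the observed within/cross split is tested with a
1-df chi-square, no continuity correction.

## Rank-products differential expression

For a two-class unpaired design every case replicate is compared with every
control replicate (the Breitling all-pairs convention; with 3 vs 3
replicates, k = 9 comparisons). Within each comparison genes are ranked by
log2 fold change (rank 1 = most up-regulated; ties receive average ranks);
a gene's rank product is the geometric mean of its ranks, computed
separately for the up- and down-regulation directions (the down statistic
equals the up statistic on sign-flipped fold changes).

Significance comes from a permutation null that shuffles gene identity
within each **sample** column and recomputes fold changes and rank
products. Permuting at sample level rather than per derived comparison
matters: all-pairs comparisons share replicate noise, and a null that
shuffles the nine comparison columns independently under-disperses the rank
products and rejects ~3× too often at α = 0.05 under the global null. With
sample-level permutation the measured type-I rate sits inside the exact
binomial 99% interval around 0.05 over 200 replicate null datasets.

Null rank products are pooled over genes and permutations: for gene g,
p(g) = (1 + #{null rp ≤ rp(g)}) / (1 + n_perm·G), and the expected number
of false positives per permutation divided by the gene's rank gives pfp
(the rank-products analogue of FDR), made non-decreasing along the rp
ordering by a step-up pass. The downstream hit list defaults to p < 0.05 on
the up-regulation tail.

## Monte Carlo enrichment

For a hit list of size h against a background of N annotated genes, each of
`n_resamples` (default 10,000) draws takes h genes uniformly without
replacement and counts per-category annotations. The mean and SD of those
counts are the expected representation and its spread; the add-one
upper-tail p measures over-representation and converges to the
hypergeometric tail (verified against the closed form). p-values are
Benjamini–Hochberg adjusted across an explicit family size m, which may
exceed the number of categories in the call — the convention when only a
subset of a fixed family of m tested subcategories is reported (default
m = 21 in the pipeline). `bh_adjust` is written in-house because the
standard step-up implementations tie m to the vector length.

A packaged fixture ships a 31-gene × 6-category membership table of
immune-system-associated genes up-regulated in TNF-alpha-stimulated
sympathetic neuron cultures; its exact per-category counts
(22/22/9/19/13/6) are the package's exact worked example.

## Ontology handling

Annotations are propagated child → parent along is_a edges only (part_of
is off by default but available); a gene reaching an ancestor along
multiple paths counts once, propagation is idempotent, and cyclic input is
rejected with a cycle named. Any provided annotation table is treated as
authoritative — no live GO fetching or release reconciliation.

## Synthetic data: what it emulates and what it does not

`generate_module_matrix` uses a single-factor Gaussian model: within a
module of correlation ρ, x = √ρ·f + √(1−ρ)·ε with a shared standard-normal
factor per sample, giving expected within-module correlation exactly ρ and
zero across modules. Modules may share a latent factor (declared by a
factor group), in which case genes of two coupled modules correlate at
√(ρ₁ρ₂) — used to plant cross-set co-expression. Everything downstream is
rank- or correlation-based, so a Gaussian emulation captures the relevant
structure; what it does **not** emulate is count-scale noise,
mean–variance coupling, batch effects, or developmental-trajectory
autocorrelation. Passing tests therefore demonstrate correctness of the
statistics and their nulls, not robustness to those real-data features.

The reference module study (`planted_module_study`) uses 2,000 genes × 100
samples: an IS set of 70 genes in two ρ = 0.9 modules (45 + 25) and an NS
set of 50 genes in two ρ = 0.3 modules sharing the larger IS module's
factor. Two design constraints fixed these numbers. First, with m
equally-sized modules only ~1/m of within-set pairs are module pairs, so a
*median* statistic only reflects the planted signal when a single set is
concentrated in very few modules; the 45 + 25 split puts 53% of within-IS
pairs inside modules, placing the median robustly in the elevated mass
while still leaving two cliques between which edge swaps can move (one
clique alone is rigid under the null). Second, module correlation 0.9 is
needed for the R > 0.9 threshold to retain edges at 100 samples: a ρ = 0.8
module essentially never produces sample correlations above 0.9 (a ≈ 3.7
SD event on the Fisher-z scale), so sweeps to 0.9 require ρ = 0.9 modules.

`generate_de_experiment` draws per-gene baseline log2 intensities
~N(8, 1), adds unit-variance replicate noise, shifts a planted fraction
(default 5%) of genes upward in the case condition, and returns 2^x
intensities. The effect size is expressed in SD units of a single
case-minus-control log2 fold-change comparison — the noise scale the rank
statistics actually see; at the default δ = 2 and 3 vs 3 replicates the
rank product recovers ≈ 85% of planted genes in the top-|planted| list
(with δ defined against per-replicate noise instead, no statistic can
exceed ≈ 63% recovery at these sizes, which is why the comparison scale is
the meaningful one). Planted genes can be concentrated inside a labelled
set to emulate a stimulation experiment whose responders fall in one
functional category.

## Numerical choices

- Empirical p-values are always add-one (Davison–Hinkley), floor
  1/(n+1); Z-scores use the sample SD; a degenerate null (zero SD) gives
  z = NaN with p still defined.
- Thresholds are strict (> not ≥) for both correlation cutoffs and the
  negative-control filter, by the literal reading of their definitions.
- The correlation matrix is explicitly symmetrized ((R + Rᵀ)/2): BLAS
  `corrcoef` output is not bit-symmetric, and un-symmetrized values make
  resampling nulls depend on the order in which a pair is drawn.
- One integer seed governs each stochastic operation via
  `numpy.random.default_rng`; observed statistics are seed-free, only null
  distributions and p-values move with the seed.
- Clustering-ratio bands for null controls are evaluated on the ratio
  averaged over replicate graphs: a single 50-node graph's mean clustering
  is noisy enough (per-graph ratios 0.7–1.45 on ER graphs) that a band of
  [0.8, 1.25] is only a meaningful statement about the average.

## Problem sizes used in the test suite

Calibration checks use 200 replicate null datasets (100 genes × 20 samples
for the co-expression test; 40 genes, 3 vs 3 for rank products) with
199-draw and 25-permutation nulls respectively — small nulls are fine for
calibration because the add-one estimator's rejection rule is exact under
exchangeability. Structure-recovery checks run the full 2,000-gene
reference studies with 99–1,000-draw nulls. These sizes were chosen so the
whole suite documents the method at realistic scale while remaining quick
to run routinely.

## Known limitations

- The degree-preserving null randomizes topology only; it does not model
  the PSD-transitivity of correlation graphs (see above), so ratios on
  real data should be compared against the shuffle control, not 1.0.
- The expected-fraction model of the edge-composition test ((f−1)/(n−1)
  under random partner choice) is one defensible null among several; it
  ignores degree heterogeneity between focal and non-focal nodes.
- Rank products assume exchangeable replicates within each class; no
  moderated-variance modelling is attempted.
- GMT/OBO inputs are taken at face value; identifier namespaces are not
  reconciled.
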