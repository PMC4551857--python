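# neurocoex

Resampling-based analysis of coordinated gene expression for labelled gene
sets — built for the question of whether immune-system (IS) genes are
co-expressed as an organized module inside nervous-system transcriptomes,
but applicable to any named set of genes in any genes × samples expression
matrix.

It is aimed at computational biologists who want the full chain —
preprocessing, set-level co-expression statistics, network clustering
against degree-preserving nulls, rank-products differential expression,
and Monte Carlo GO enrichment — as reusable, tested library code with a
thin CLI, plus a synthetic-data generator that plants known structure so
every stage can be validated without downloading anything.

## The statistics

**Set co-expression.** For a gene set A, the statistic is the median
Pearson correlation over all distinct pairs in A (or all cross pairs
between two disjoint sets). Its null is the same median in `n` equally
sized random gene sets drawn from the background; the observed value is
reported as Z = (obs − mean(null))/sd(null) and as the add-one empirical
p = (1 + #{null ≥ obs}) / (1 + n).

**Network clustering.** Pairs with correlation strictly above a cutoff R
form a graph; the mean Watts–Strogatz local clustering coefficient
C = 2T/(k(k−1)) (nodes with k < 2 excluded) is compared with the same
quantity in random networks produced by double-edge-swap rewiring — every
null network keeps the observed degree sequence exactly. Reported: the
observed/expected ratio and an empirical p, optionally across a threshold
sweep. A 1-df chi-square tests whether edges incident to the focal set are
within-set more often than the random-partner expectation (f−1)/(n−1).

**Differential expression.** Rank products: per case–control comparison,
genes are ranked by log2 fold change; a gene's score is the geometric mean
of its ranks across all comparisons, with p-values from sample-level
permutations pooled over genes and pfp (proportion of false positives) as
the FDR analogue.

**Enrichment.** Observed counts of hit-list genes per GO category versus
the count distribution in equally sized random draws from the background
(converges to the hypergeometric law), with Benjamini–Hochberg adjustment
across an explicit family size m.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

Plant two strongly co-regulated modules (ρ = 0.9) hosting an "IS" set of
40 genes inside a 500-gene, 80-sample matrix, then measure set-level
co-expression and clustering against their nulls:

```python
from neurocoex import (
    SyntheticConfig, generate_module_matrix, correlation_matrix,
    set_coexpression_test, build_threshold_graph, degree_preserving_null,
)

cfg = SyntheticConfig(
    n_genes=500, n_samples=80,
    modules=[(25, 0.9, "a"), (15, 0.9, "b")],
    set_labels={"IS": [0, 1]},
    seed=7,
)
expr, truth = generate_module_matrix(cfg)
cm = correlation_matrix(expr)
is_genes = truth["sets"]["IS"]

res = set_coexpression_test(cm, is_genes, n_resamples=1000, seed=7)
print(f"observed median r = {res.observed_median:.3f}")
print(f"Z = {res.z_score:.1f}, empirical p = {res.p_empirical:.4g}")

graph = build_threshold_graph(cm, 0.9, is_genes, scope="within_set")
null = degree_preserving_null(graph, n_networks=199, seed=7)
print(f"graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
print(f"clustering ratio = {null.ratio:.2f}, p = {null.p_empirical:.4g}")
```

Output:

```
observed median r = 0.858
Z = 158.1, empirical p = 0.000999
graph: 38 nodes, 103 edges
clustering ratio = 1.35, p = 0.005
```

The set's median pairwise correlation (0.858) sits 158 null standard
deviations above the random-set expectation, with the smallest p the
1,000-draw null can produce (add-one floor 1/1001). At the R > 0.9 cutoff
the set's network keeps 103 edges over 38 nodes and is 1.35× more
clustered than degree-matched random networks (p = 1/200).

The same stages are available from the shell:

```bash
neurocoex simulate  --config sim.yaml --out-dir sim/
neurocoex normalize --matrix raw.tsv --out norm.tsv
neurocoex coexpr    --matrix norm.tsv --set-a IS.gmt --n-resamples 10000 --seed 17 --out coexpr.json
neurocoex network   --matrix norm.tsv --set IS.gmt --threshold 0.9 --n-null 10000 --seed 17
neurocoex rankprod  --case case.tsv --control control.tsv --n-perm 1000 --seed 17 --out rp.tsv
neurocoex enrich    --hits hits.txt --annot annot.tsv --n-resamples 10000 --m 21 --seed 17 --out enrich.tsv
neurocoex run       --config pipeline.yaml --out-dir out/
```

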