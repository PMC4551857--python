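"""Monte Carlo gene-set enrichment with Benjamini-Hochberg adjustment.

The observed count of hit-list genes annotated to each GO category is
compared with the distribution of counts in equally sized random gene
samples drawn from the background universe; the null mean and SD give the
expected representation, and an add-one upper-tail empirical p measures
over-representation. P-values are BH-adjusted across an explicit number of
tests m, which may exceed the number of categories in the call (the
convention when only a subset of a fixed family of tested subcategories is
reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from neurocoex.gene_sets import AnnotationTable

__all__ = [
    "EnrichmentResult",
    "count_annotated",
    "mc_enrichment",
    "enrichment_table",
    "bh_adjust",
]


def count_annotated(hit_list, annot: AnnotationTable, category: str) -> int:
    """Number of hit-list genes annotated to a category (exact count)."""
    hits = frozenset(hit_list)
    stray = hits - set(annot.background_genes)
    if stray:
        raise ValueError(f"hit-list genes outside the background: {sorted(stray)[:5]}")
    return len(hits & annot.genes_in(category))


@dataclass
class EnrichmentResult:
    """Per-category Monte Carlo enrichment summary (mirrors a GO table row)."""

    category_id: str
    category_name: str
    observed_genes: int
    expected_genes: float
    sd_null: float
    p_numeric: float
    p_adjusted: float
    n_resamples: int
    seed: int


def mc_enrichment(
    hit_list,
    annot: AnnotationTable,
    categories=None,
    n_resamples: int = 10_000,
    seed: int = 0,
    m: int | None = None,
) -> list[EnrichmentResult]:
    """Monte Carlo over-representation test for each category.

    Each resample draws |hit_list| genes uniformly without replacement from
    the annotation background; per-category counts across resamples give the
    expected count, its SD, and the add-one upper-tail p. BH adjustment is
    applied across ``m`` tests (default: the number of categories tested
    here).

    Monte Carlo p-values are floored at 1/(n_resamples+1) by the add-one
    estimator; an exactly-zero p is a reporting artifact this implementation
    never produces.
    """
    hits = list(dict.fromkeys(hit_list))
    if not hits:
        raise ValueError("hit list is empty")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if categories is None:
        categories = annot.categories
    categories = list(categories)
    unknown = [c for c in categories if c not in annot.categories]
    if unknown:
        raise KeyError(f"unknown categories: {unknown}")
    observed = np.array([count_annotated(hits, annot, c) for c in categories])

    inc = annot.incidence[categories].to_numpy(dtype=float)
    n_bg = inc.shape[0]
    if len(hits) > n_bg:
        raise ValueError("hit list larger than annotation background")
    rng = np.random.default_rng(seed)
    counts = np.empty((n_resamples, len(categories)))
    for t in range(n_resamples):
        idx = rng.choice(n_bg, size=len(hits), replace=False)
        counts[t] = inc[idx].sum(axis=0)
    expected = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if n_resamples > 1 else np.zeros(len(categories))
    p = (1 + (counts >= observed).sum(axis=0)) / (1 + n_resamples)
    p_adj = bh_adjust(p, m=m if m is not None else len(categories))
    return [
        EnrichmentResult(
            category_id=c,
            category_name=annot.category_names.get(c, c),
            observed_genes=int(observed[i]),
            expected_genes=float(expected[i]),
            sd_null=float(sd[i]),
            p_numeric=float(p[i]),
            p_adjusted=float(p_adj[i]),
            n_resamples=int(n_resamples),
            seed=seed,
        )
        for i, c in enumerate(categories)
    ]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per category)."""
    return pd.DataFrame(
        {
            "category_id": [r.category_id for r in results],
            "category_name": [r.category_name for r in results],
            "observed_genes": [r.observed_genes for r in results],
            "expected_genes": [r.expected_genes for r in results],
            "sd_null": [r.sd_null for r in results],
            "p_numeric": [r.p_numeric for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted(i) = min over j ≥ i (in the sorted order) of p(j)·m/j, capped
    at 1, returned in the input order. ``m`` defaults to the number of
    p-values but may be larger when the family of tests exceeds the values
    reported (it must not be smaller).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m ({m}) must be at least the number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adjusted_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = adjusted_sorted
    return out
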