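"""Set-level co-expression statistics with Monte Carlo resampling nulls.

The central statistic is the median Pearson correlation over all distinct
gene pairs within a set (or across two disjoint sets). Its null distribution
is obtained by drawing many equally sized random gene sets from the
background population and recomputing the median each time; the observed
median is then expressed as a Z-score against that null and as an add-one
empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neurocoex.expression_io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "SetCoexpressionResult",
    "correlation_matrix",
    "median_set_coexpression",
    "resampled_null",
    "summarize_null",
    "set_coexpression_test",
]


@dataclass
class CorrelationMatrix:
    """All-pairs Pearson correlations between genes.

    ``R`` is symmetric with unit diagonal; rows/columns of zero-variance
    genes are NaN and those genes are excluded from all downstream medians,
    thresholds and resampling backgrounds.
    """

    gene_ids: list
    R: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        if self.R.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("correlation matrix shape does not match gene ids")

    def indices(self, genes) -> np.ndarray:
        try:
            return np.array([self._index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in correlation matrix") from None

    @property
    def valid_genes(self) -> list:
        """Genes with defined correlations (non-degenerate variance)."""
        ok = ~np.isnan(np.diagonal(self.R))
        return [g for g, m in zip(self.gene_ids, ok) if m]


def correlation_matrix(expr: ExpressionMatrix, log2: bool = False) -> CorrelationMatrix:
    """Pearson correlation across all gene pairs over all samples.

    Zero-variance genes yield NaN rows/columns (undefined correlation) and
    are flagged by exclusion from :attr:`CorrelationMatrix.valid_genes`.
    With ``log2=True`` values are log2-transformed before correlating
    (requires strictly positive values).
    """
    if expr.n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {expr.n_samples}")
    x = expr.values
    if log2:
        if np.any(x <= 0):
            raise ValueError("log2 transform requires strictly positive values")
        x = np.log2(x)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = (r + r.T) / 2.0  # enforce exact symmetry (corrcoef is not bit-symmetric)
    degenerate = sd == 0
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    return CorrelationMatrix(expr.gene_ids, r)


def _pair_values(cm: CorrelationMatrix, set_a, set_b=None) -> np.ndarray:
    ia = cm.indices(sorted(set_a))
    if set_b is None:
        if len(ia) < 2:
            raise ValueError("within-set mode requires at least 2 genes")
        sub = cm.R[np.ix_(ia, ia)]
        vals = sub[np.triu_indices(len(ia), k=1)]
    else:
        ib = cm.indices(sorted(set_b))
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError("between-set mode requires two non-empty sets")
        vals = cm.R[np.ix_(ia, ib)].ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined gene pairs (all pairs degenerate)")
    return vals


def median_set_coexpression(cm: CorrelationMatrix, set_a, set_b=None) -> float:
    """Median pairwise correlation within ``set_a`` or across two sets.

    Within-set mode uses the |A|(|A|−1)/2 unordered distinct pairs;
    between-set mode all |A|×|B| cross pairs. Self-pairs never contribute;
    undefined (zero-variance) pairs are excluded.
    """
    return float(np.median(_pair_values(cm, set_a, set_b)))


def resampled_null(
    cm: CorrelationMatrix,
    set_sizes,
    background,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null medians from random equally sized gene sets.

    ``set_sizes`` is either a single int (within-set mode) or a pair of ints
    (between-set mode: the two disjoint random sets are drawn jointly).
    Draws are uniform without replacement from ``background`` (restricted to
    genes with defined correlations), independent across resamples.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    valid = set(cm.valid_genes)
    bg = cm.indices([g for g in background if g in valid])
    if np.isscalar(set_sizes):
        sizes = (int(set_sizes),)
    else:
        sizes = tuple(int(s) for s in set_sizes)
    total = sum(sizes)
    if total > bg.size:
        raise ValueError(
            f"background of {bg.size} usable genes cannot supply {total} genes"
        )
    medians = np.empty(n_resamples)
    for t in range(n_resamples):
        draw = rng.choice(bg, size=total, replace=False)
        if len(sizes) == 1:
            sub = cm.R[np.ix_(draw, draw)]
            vals = sub[np.triu_indices(total, k=1)]
        else:
            a, b = draw[: sizes[0]], draw[sizes[0]:]
            vals = cm.R[np.ix_(a, b)].ravel()
        medians[t] = np.median(vals)
    return medians


@dataclass
class SetCoexpressionResult:
    """Observed set-level median correlation against its resampling null."""

    observed_median: float
    null_medians: np.ndarray
    z_score: float
    p_empirical: float
    n_resamples: int
    seed: int | None = None
    tail: str = "upper"


def summarize_null(
    observed: float, null_medians, tail: str = "upper", seed: int | None = None
) -> SetCoexpressionResult:
    """Z-score and add-one empirical p-value of an observed statistic.

    z = (observed − mean(null)) / sd(null) with the sample SD (n−1);
    p = (1 + #{null ≥ observed}) / (1 + n) for the upper tail (≤ for the
    lower tail). A degenerate null (zero SD) yields z = NaN but p is still
    defined.
    """
    null = np.asarray(null_medians, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    mean = null.mean()
    sd = null.std(ddof=1) if null.size > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else float("nan")
    if tail == "upper":
        exceed = int(np.sum(null >= observed))
    elif tail == "lower":
        exceed = int(np.sum(null <= observed))
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    p = (1 + exceed) / (1 + null.size)
    return SetCoexpressionResult(
        observed_median=float(observed),
        null_medians=null,
        z_score=float(z),
        p_empirical=float(p),
        n_resamples=int(null.size),
        seed=seed,
        tail=tail,
    )


def set_coexpression_test(
    cm: CorrelationMatrix,
    set_a,
    set_b=None,
    background=None,
    n_resamples: int = 10_000,
    seed: int = 0,
    tail: str = "upper",
) -> SetCoexpressionResult:
    """Convenience wrapper: observed median, resampling null, and summary."""
    if background is None:
        background = cm.valid_genes
    observed = median_set_coexpression(cm, set_a, set_b)
    sizes = len(set(set_a)) if set_b is None else (len(set(set_a)), len(set(set_b)))
    null = resampled_null(cm, sizes, background, n_resamples=n_resamples, seed=seed)
    return summarize_null(observed, null, tail=tail, seed=seed)
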