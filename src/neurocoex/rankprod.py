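"""Rank-products differential expression with a permutation null.

For each case–control comparison genes are ranked by fold change (rank 1 =
strongest change in the tested direction, ties averaged); a gene's rank
product is the geometric mean of its ranks across comparisons. Consistently
up- (or down-) regulated genes have small rank products. Significance comes
from a permutation null that independently shuffles the gene assignment of
fold changes within every comparison, pooling null rank products over genes
and permutations; the per-gene expected-false-positive count divided by the
gene's rank gives the estimated proportion of false positives (pfp), the
rank-products analogue of FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from neurocoex.expression_io import ExpressionMatrix

__all__ = ["RankProductResult", "rank_product", "permutation_pvalues", "rank_product_analysis"]


def _comparison_logfc(expr_case: ExpressionMatrix, expr_control: ExpressionMatrix) -> np.ndarray:
    """Genes × comparisons matrix of log2 fold changes.

    Unpaired two-class design: every case sample is compared with every
    control sample, giving k = n_case × n_control comparisons. Expression is
    assumed positive (intensity scale); fold change is the case/control
    ratio, log2-transformed before ranking.
    """
    if expr_case.gene_ids != expr_control.gene_ids:
        raise ValueError("case and control matrices must share the same gene universe")
    case, ctrl = expr_case.values, expr_control.values
    if np.any(case <= 0) or np.any(ctrl <= 0):
        raise ValueError("rank products require strictly positive expression values")
    # broadcast: genes × (n_case·n_control)
    lfc = np.log2(case[:, :, None] / ctrl[:, None, :])
    return lfc.reshape(case.shape[0], -1)


def _rank_products_from_logfc(lfc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(rp_up, rp_down) geometric-mean ranks; rank 1 = strongest change."""
    up_ranks = stats.rankdata(-lfc, method="average", axis=0)
    down_ranks = stats.rankdata(lfc, method="average", axis=0)
    rp_up = np.exp(np.mean(np.log(up_ranks), axis=1))
    rp_down = np.exp(np.mean(np.log(down_ranks), axis=1))
    return rp_up, rp_down


def rank_product(
    expr_case: ExpressionMatrix, expr_control: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene rank products for up- and down-regulation.

    Returns a DataFrame indexed by gene with columns ``rp_up`` and
    ``rp_down``. Ties within a comparison receive average ranks.
    """
    lfc = _comparison_logfc(expr_case, expr_control)
    rp_up, rp_down = _rank_products_from_logfc(lfc)
    return pd.DataFrame({"rp_up": rp_up, "rp_down": rp_down}, index=expr_case.gene_ids)


@dataclass
class RankProductResult:
    """Rank products with permutation p-values and pfp estimates."""

    table: pd.DataFrame  # gene-indexed: rp_up, p_up, pfp_up, rp_down, p_down, pfp_down
    n_permutations: int
    seed: int

    def significant_up(self, alpha: float = 0.05) -> list:
        """Genes with up-regulation permutation p below ``alpha``."""
        t = self.table
        return list(t.index[t["p_up"] < alpha])


def _null_tail_stats(rp_obs: np.ndarray, null_rps: np.ndarray, n_perm: int):
    """Add-one p and pfp from pooled null rank products (small rp = extreme)."""
    g = rp_obs.size
    null_sorted = np.sort(null_rps)
    counts = np.searchsorted(null_sorted, rp_obs, side="right")
    p = (1 + counts) / (1 + n_perm * g)
    order_rank = stats.rankdata(rp_obs, method="average")
    pfp = (counts / n_perm) / order_rank
    # enforce monotonicity along the rp ordering (step-up, as for FDR curves)
    order = np.argsort(rp_obs, kind="stable")
    pfp[order] = np.maximum.accumulate(pfp[order])
    return p, pfp


def permutation_pvalues(
    expr_case: ExpressionMatrix,
    expr_control: ExpressionMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RankProductResult:
    """Permutation p-values and pfp for both regulation directions.

    Each permutation shuffles which gene carries which value within every
    sample column (independently per column) and recomputes fold changes
    and rank products, so the null preserves the dependence among
    comparisons that share a replicate; a gene's p-value is the
    add-one-corrected fraction of pooled null rank products at least as
    small as its observed one, and pfp divides the expected number of such
    null values per permutation by the gene's rank.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    lfc = _comparison_logfc(expr_case, expr_control)
    g = lfc.shape[0]
    rp_up, rp_down = _rank_products_from_logfc(lfc)
    log_case = np.log2(expr_case.values)
    log_ctrl = np.log2(expr_control.values)
    null_up = np.empty((n_permutations, g))
    null_down = np.empty((n_permutations, g))
    for t in range(n_permutations):
        pc = np.column_stack(
            [log_case[rng.permutation(g), j] for j in range(log_case.shape[1])]
        )
        pk = np.column_stack(
            [log_ctrl[rng.permutation(g), j] for j in range(log_ctrl.shape[1])]
        )
        perm = (pc[:, :, None] - pk[:, None, :]).reshape(g, -1)
        nu, nd = _rank_products_from_logfc(perm)
        null_up[t] = nu
        null_down[t] = nd
    p_up, pfp_up = _null_tail_stats(rp_up, null_up.ravel(), n_permutations)
    p_down, pfp_down = _null_tail_stats(rp_down, null_down.ravel(), n_permutations)
    table = pd.DataFrame(
        {
            "rp_up": rp_up,
            "p_up": p_up,
            "pfp_up": pfp_up,
            "rp_down": rp_down,
            "p_down": p_down,
            "pfp_down": pfp_down,
        },
        index=expr_case.gene_ids,
    )
    return RankProductResult(table=table, n_permutations=n_permutations, seed=seed)


def rank_product_analysis(
    expr_case: ExpressionMatrix,
    expr_control: ExpressionMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RankProductResult:
    """Alias for :func:`permutation_pvalues` (full rank-products analysis)."""
    return permutation_pvalues(expr_case, expr_control, n_permutations, seed)
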