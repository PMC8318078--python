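"""Differential expression and the mitral-cell marker screen.

Genes are ranked between the putative MC cluster and the tufted-cell
comparison clusters with the two-sided Mann-Whitney U test, p values are
adjusted with the Benjamini-Hochberg step-up procedure, and candidates are
screened with three rules:

* significant — adjusted p below ``alpha`` (default 0.05);
* consistent_in_MC — expressed above ``expr_threshold`` (default 3, in
  log2(count+1) units) in more than ``inside_frac`` (default 50%) of MC cells;
* absent_outside — expressed above threshold in fewer than ``outside_frac``
  (default 10%) of cells within every comparison cluster, evaluated per
  cluster.

A marker is a gene passing all three.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


def mwu_test(x, y) -> float:
    """Two-sided Mann-Whitney U p value.

    Uses the exact null distribution when both groups have at most 8
    observations and there are no ties, the tie-corrected normal
    approximation otherwise (scipy's ``method='auto'`` rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(sstats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def expressing_fraction(expr_rows: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Per-gene fraction of cells with expression above threshold."""
    expr_rows = np.atleast_2d(expr_rows)
    return (expr_rows > threshold).mean(axis=1)


def screen_markers(
    log_expr,
    gene_names,
    mc_mask,
    comparison_masks,
    alpha: float = 0.05,
    expr_threshold: float = 3.0,
    inside_frac: float = 0.5,
    outside_frac: float = 0.1,
    pool_comparison: bool = True,
    use_median_rule: bool = False,
) -> pd.DataFrame:
    """Build the marker table for MC vs the comparison (TC) clusters.

    ``comparison_masks`` is a list of boolean cell masks, one per non-MC
    cluster; by default their union is pooled for the U test while the
    absent-outside rule is evaluated within each cluster separately (the
    strictest reading).  ``use_median_rule`` swaps the consistency rule to
    "median MC expression above threshold".

    Returns a DataFrame indexed by gene with mean expression, p values,
    expressing fractions and the three pass flags plus ``marker``.
    """
    log_expr = np.asarray(log_expr, dtype=float)
    gene_names = np.asarray(gene_names, dtype=object)
    mc_mask = np.asarray(mc_mask, dtype=bool)
    comparison_masks = [np.asarray(m, dtype=bool) for m in comparison_masks]
    if mc_mask.sum() == 0:
        raise ValueError("no MC cluster assigned")
    if not comparison_masks or all(m.sum() == 0 for m in comparison_masks):
        raise ValueError("need at least one non-empty comparison cluster")
    comparison_masks = [m for m in comparison_masks if m.sum() > 0]

    mc = log_expr[:, mc_mask]
    if pool_comparison:
        pooled = np.logical_or.reduce(comparison_masks)
        tc_sets = [log_expr[:, pooled]]
    else:
        tc_sets = [log_expr[:, m] for m in comparison_masks]

    # vectorized U test across genes; min p across comparison sets if unpooled
    pvals = np.ones(log_expr.shape[0])
    for tc in tc_sets:
        res = sstats.mannwhitneyu(mc, tc, alternative="two-sided", method="auto", axis=1)
        pvals = np.minimum(pvals, res.pvalue)
    adj = bh_adjust(pvals)

    frac_mc = expressing_fraction(mc, expr_threshold)
    frac_out = np.column_stack(
        [expressing_fraction(log_expr[:, m], expr_threshold) for m in comparison_masks]
    )
    max_frac_out = frac_out.max(axis=1)

    if use_median_rule:
        consistent = np.median(mc, axis=1) > expr_threshold
    else:
        consistent = frac_mc > inside_frac
    significant = adj < alpha
    absent_outside = (frac_out < outside_frac).all(axis=1)

    table = pd.DataFrame(
        {
            "mean_mc": mc.mean(axis=1),
            "pvalue": pvals,
            "adj_pvalue": adj,
            "frac_mc": frac_mc,
            "max_frac_non_mc": max_frac_out,
            "significant": significant,
            "consistent_in_mc": consistent,
            "absent_outside": absent_outside,
        },
        index=pd.Index(gene_names, name="gene"),
    )
    table["marker"] = significant & consistent & absent_outside
    return table.sort_values(["marker", "adj_pvalue"], ascending=[False, True], kind="stable")
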