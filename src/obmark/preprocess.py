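"""Count transformation and overdispersed-gene selection.

Counts are log-transformed as log2(count + 1).  For each gene x the
overdispersion statistic is the log Fano factor

    F_x = log10(sigma^2_x / mu_x)

where mu_x and sigma^2_x are the mean and variance of the (log) expression
across cells.  Because F_x varies systematically with expression level,
genes are split into ``n_bins`` equal-count subsets ordered by mean
expression, and F_x is Z-scored within each subset:

    Z_x = (F_x - mean(F)) / std(F)   within the gene's bin.

The top-k genes by Z_x (default 500) are the overdispersed set used for
embedding and clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)


def log_transform(counts: np.ndarray) -> np.ndarray:
    """Elementwise log2(count + 1)."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return np.log2(counts + 1.0)


def gene_stats(expr: np.ndarray, gene_names=None, n_bins: int = 20) -> pd.DataFrame:
    """Per-gene mean, variance, log10 Fano factor and binned Z score.

    ``expr`` is genes x cells (log-transformed by convention; the raw-count
    ordering is selectable upstream).  Genes with zero mean or zero variance
    are flagged ``eligible=False`` and excluded from binning rather than
    carried as sentinel values.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2:
        raise ValueError("expr must be genes x cells")
    n_genes = expr.shape[0]
    if gene_names is None:
        gene_names = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    gene_names = np.asarray(gene_names, dtype=object)

    mu = expr.mean(axis=1)
    var = expr.var(axis=1, ddof=1) if expr.shape[1] > 1 else np.zeros(n_genes)
    eligible = (mu > 0) & (var > 0)

    fano = np.full(n_genes, np.nan)
    fano[eligible] = np.log10(var[eligible] / mu[eligible])

    stats = pd.DataFrame(
        {"mean": mu, "variance": var, "fano": fano, "eligible": eligible},
        index=pd.Index(gene_names, name="gene"),
    )
    stats["bin"] = -1
    stats["zscore"] = np.nan

    idx = np.flatnonzero(eligible)
    if idx.size:
        bins = equal_count_bins(mu[idx], n_bins)
        stats.iloc[idx, stats.columns.get_loc("bin")] = bins
        z = np.full(idx.size, np.nan)
        for b in range(bins.max() + 1):
            sel = bins == b
            f = fano[idx][sel]
            sd = f.std(ddof=1) if sel.sum() > 1 else 0.0
            if sd > 0:
                z[sel] = (f - f.mean()) / sd
            else:
                logger.warning("fano bin %d has zero SD; Z set to 0", b)
                z[sel] = 0.0
        stats.iloc[idx, stats.columns.get_loc("zscore")] = z
    return stats


def equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Partition into n_bins contiguous equal-count groups ordered by value.

    Ties in ``values`` are resolved by original index, making the partition
    deterministic.  When len(values) < n_bins, each value gets its own bin.
    """
    values = np.asarray(values)
    n = values.size
    n_bins = min(n_bins, n)
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    # np.array_split semantics: first (n % n_bins) bins get the extra gene
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    for b in range(n_bins):
        bins[order[edges[b] : edges[b + 1]]] = b
    return bins


def select_overdispersed(stats: pd.DataFrame, k: int = 500) -> list[str]:
    """The k genes with the largest binned Z score.

    Ties at the cutoff break by lexicographic gene name, so the selection is
    independent of input gene order.
    """
    eligible = stats.loc[stats["eligible"]]
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds the {len(eligible)} eligible genes")
    ranked = eligible.assign(_name=eligible.index.astype(str)).sort_values(
        ["zscore", "_name"], ascending=[False, True], kind="stable"
    )
    return list(ranked.index[:k])


class OverdispersedGeneSelector(SelectorMixin, BaseEstimator):
    """Select the top-k overdispersed genes by mean-binned Fano-factor Z score.

    Follows the sklearn feature-selection API: ``X`` is cells x genes.

    Parameters
    ----------
    n_top : int
        Number of genes to keep (default 500).
    n_bins : int
        Equal-count mean-expression bins for Z-scoring (default 20).
    on_log : bool
        Compute Fano statistics on log2(count+1) values (default) or on the
        raw counts.

    Attributes
    ----------
    gene_stats_ : DataFrame with per-gene mean, variance, fano, bin, zscore.
    selected_genes_ : list of selected gene names.
    """

    def __init__(self, n_top: int = 500, n_bins: int = 20, on_log: bool = True):
        self.n_top = n_top
        self.n_bins = n_bins
        self.on_log = on_log

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_features=2, dtype=float)
        names = getattr(self, "feature_names_in_", None)
        expr = X.T  # genes x cells
        if self.on_log:
            expr = log_transform(expr)
        self.gene_stats_ = gene_stats(expr, gene_names=names, n_bins=self.n_bins)
        self.selected_genes_ = select_overdispersed(self.gene_stats_, k=self.n_top)
        sel = set(self.selected_genes_)
        self.support_ = np.asarray(
            [g in sel for g in self.gene_stats_.index], dtype=bool
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
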