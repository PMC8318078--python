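"""Dimensionality reduction, density clustering and cluster-role assignment.

The expression matrix (restricted to the overdispersed gene set) is reduced
with PCA to 10 components and embedded into 2-D with tSNE (learning rate 10,
perplexity 33).  HDBSCAN (min_cluster_size 5, min_samples 13) clusters the
embedding; noise labels (-1) are allowed and excluded from all role logic.

Roles are assigned from marker genes: the cluster with the highest mean
Tbx21 holds the mitral + Tbx21-positive tufted population; within its
subclusters, the one with the lowest fraction of cells expressing Cck above
threshold 3 (log2 counts) is the putative mitral-cell (MC) cluster; the
remaining Tbx21 subclusters are TC1.  TC2 is the set of Cck-rich,
glutamatergic (Slc17a7-positive) clusters outside the Tbx21 cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus per-cluster role tags."""

    labels: np.ndarray  # int per cell, -1 = noise
    roles: dict[int, str] = field(default_factory=dict)  # cluster id -> role

    def cells_with_role(self, role: str) -> np.ndarray:
        ids = [c for c, r in self.roles.items() if r == role]
        return np.isin(self.labels, ids)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(c for c in np.unique(self.labels) if c != -1)


class TSNEEmbedder(BaseEstimator):
    """PCA to ``n_pcs`` components followed by 2-D tSNE.

    Parameters mirror the analysis defaults: 10 PCs, learning rate 10,
    perplexity 33.  ``fit_transform`` is the only supported path (tSNE has no
    out-of-sample transform); the embedding is stored as ``embedding_``.
    """

    def __init__(self, n_pcs: int = 10, learning_rate: float = 10.0,
                 perplexity: float = 33.0, random_state: int | None = 0):
        self.n_pcs = n_pcs
        self.learning_rate = learning_rate
        self.perplexity = perplexity
        self.random_state = random_state

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_cells = X.shape[0]
        if n_cells <= 3 * self.perplexity:
            raise ValueError(
                f"tSNE requires more than 3 x perplexity = {3 * self.perplexity:.0f} "
                f"cells; got {n_cells} (lower the perplexity)"
            )
        self.pca_ = PCA(n_components=min(self.n_pcs, min(X.shape) - 1),
                        random_state=self.random_state)
        pcs = self.pca_.fit_transform(X)
        tsne = TSNE(
            n_components=2,
            learning_rate=self.learning_rate,
            perplexity=self.perplexity,
            init="pca",
            random_state=self.random_state,
        )
        self.embedding_ = tsne.fit_transform(pcs)
        return self.embedding_

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def embed(log_expr_cells_by_genes, n_pcs=10, learning_rate=10.0, perplexity=33.0,
          seed: int | None = 0) -> np.ndarray:
    """Functional wrapper over :class:`TSNEEmbedder`."""
    return TSNEEmbedder(n_pcs, learning_rate, perplexity, seed).fit_transform(
        log_expr_cells_by_genes
    )


class DensityClusterer(BaseEstimator):
    """HDBSCAN on a 2-D embedding with the analysis defaults.

    min_cluster_size=5 is the smallest allowed cluster; min_samples=13 is the
    neighbor rank used for core distances.
    """

    def __init__(self, min_cluster_size: int = 5, min_samples: int = 13):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.min_samples:
            raise ValueError(
                f"need at least min_samples={self.min_samples} cells, got {X.shape[0]}"
            )
        if np.allclose(X, X[0]):  # fully degenerate: one point repeated
            self.labels_ = np.zeros(X.shape[0], dtype=int)
            return self
        h = HDBSCAN(min_cluster_size=self.min_cluster_size,
                    min_samples=self.min_samples, copy=True)
        self.labels_ = h.fit_predict(X)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster(embedding: np.ndarray, min_cluster_size: int = 5,
            min_samples: int = 13) -> ClusterAssignment:
    labels = DensityClusterer(min_cluster_size, min_samples).fit_predict(embedding)
    return ClusterAssignment(labels=labels)


# ---------------------------------------------------------------------------
# role assignment


def _gene_row(log_expr, gene_names, gene):
    gene_names = np.asarray(gene_names, dtype=object)
    hits = np.flatnonzero(gene_names == gene)
    if hits.size == 0:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    return np.asarray(log_expr)[hits[0]]


def find_marker_rich_cluster(assignment: ClusterAssignment, log_expr, gene_names,
                             gene: str = "Tbx21") -> int:
    """The non-noise cluster with the highest mean expression of ``gene``.

    Ties break toward the larger cluster, then the smaller label.
    """
    expr = _gene_row(log_expr, gene_names, gene)
    ids = assignment.cluster_ids
    if not ids:
        raise ValueError("no non-noise clusters")
    stats = []
    for c in ids:
        sel = assignment.labels == c
        stats.append((expr[sel].mean(), sel.sum(), -c))
    best = max(range(len(ids)), key=lambda i: stats[i])
    if stats[best][0] == 0:
        logger.warning("no cluster expresses %s; falling back to the tie rule", gene)
    return ids[best]


def marker_fraction(log_expr, gene_names, cell_mask, gene: str,
                    threshold: float = 3.0) -> float:
    """Fraction of cells in the cluster expressing ``gene`` above threshold."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise ValueError("empty cluster")
    expr = _gene_row(log_expr, gene_names, gene)[cell_mask]
    return float((expr > threshold).sum() / expr.size)


def assign_putative_mc(assignment: ClusterAssignment, log_expr, gene_names,
                       gene: str = "Cck", threshold: float = 3.0) -> ClusterAssignment:
    """Tag the subcluster with the lowest Cck-expressing fraction as MC.

    The remaining subclusters are tagged TC1.  Ties break by the lowest mean
    expression of ``gene``, then the smallest label.
    """
    ids = assignment.cluster_ids
    if len(ids) < 2:
        raise ValueError("putative-MC rule needs at least 2 subclusters")
    expr = _gene_row(log_expr, gene_names, gene)
    keyed = []
    for c in ids:
        sel = assignment.labels == c
        frac = marker_fraction(log_expr, gene_names, sel, gene, threshold)
        keyed.append((frac, expr[sel].mean(), c))
    mc = min(keyed)[2]
    assignment.roles = {c: ("MC" if c == mc else "TC1") for c in ids}
    return assignment


def define_tc2(assignment: ClusterAssignment, log_expr, gene_names,
               tbx21_cluster, cck_gene: str = "Cck", glut_gene: str = "Slc17a7",
               threshold: float = 3.0, frac_cutoff: float = 0.5) -> list[int]:
    """Cck-rich, glutamatergic clusters outside the Tbx21-rich cluster(s).

    A cluster qualifies when its above-threshold expressing fraction exceeds
    ``frac_cutoff`` for both Cck and the glutamatergic marker.  May be empty.
    ``tbx21_cluster`` is a cluster id or an iterable of ids to exclude.
    """
    excluded = {tbx21_cluster} if np.isscalar(tbx21_cluster) else set(tbx21_cluster)
    tc2 = []
    for c in assignment.cluster_ids:
        if c in excluded:
            continue
        sel = assignment.labels == c
        if (
            marker_fraction(log_expr, gene_names, sel, cck_gene, threshold) > frac_cutoff
            and marker_fraction(log_expr, gene_names, sel, glut_gene, threshold) > frac_cutoff
        ):
            tc2.append(c)
    if not tc2:
        logger.warning("no cluster qualifies as TC2")
    for c in tc2:
        assignment.roles[c] = "TC2"
    return tc2
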