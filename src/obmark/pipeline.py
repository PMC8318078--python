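"""End-to-end marker discovery: selection, embedding, clustering, screening.

:class:`MarkerDiscovery` is an sklearn-style estimator over a cells x genes
count matrix.  ``fit`` runs the full analysis the package exists for:

1. log2(count+1) transform and top-500 overdispersed gene selection;
2. PCA (10 PCs) + tSNE embedding of all cells, HDBSCAN clustering;
3. identification of the Tbx21-rich cluster, re-embedding and subclustering
   of its cells, and assignment of the putative MC cluster (lowest fraction
   of Cck-expressing cells), with the remaining subclusters as TC1;
4. definition of TC2 (Cck-rich, glutamatergic clusters outside Tbx21);
5. the Mann-Whitney / Benjamini-Hochberg marker screen of MC vs TC1+TC2.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import __version__
from .cluster import (
    ClusterAssignment,
    DensityClusterer,
    TSNEEmbedder,
    assign_putative_mc,
    define_tc2,
    find_marker_rich_cluster,
    marker_fraction,
)
from .io import ExpressionMatrix, read_matrix
from .markers import screen_markers
from .preprocess import OverdispersedGeneSelector, log_transform

logger = logging.getLogger(__name__)


class MarkerDiscovery(BaseEstimator):
    """Discover cell-type-specific marker genes for the mitral-cell cluster.

    Parameters follow the analysis defaults throughout; every threshold is a
    constructor argument, never hard-coded.  ``X`` passed to :meth:`fit` is
    cells x genes (sklearn orientation); ``gene_names`` may be given as a
    DataFrame column index or via the ``gene_names`` argument.

    Attributes (after fit)
    ----------------------
    gene_stats_ : per-gene overdispersion statistics.
    selected_genes_ : the overdispersed gene set used for embedding.
    embedding_ : cells x 2 tSNE coordinates (whole dataset).
    labels_ : whole-dataset HDBSCAN labels (-1 = noise).
    tbx21_cluster_ : label of the Tbx21-rich cluster.
    sub_embedding_, sub_labels_ : subclustering of the Tbx21-rich cells.
    roles_ : per-cell role in {"MC", "TC1", "TC2", "other", "noise"}.
    marker_table_ : the screening table (gene-indexed DataFrame).
    markers_ : genes passing all three screening rules.
    """

    def __init__(
        self,
        n_top_genes: int = 500,
        n_bins: int = 20,
        fano_on_log: bool = True,
        n_pcs: int = 10,
        learning_rate: float = 10.0,
        perplexity: float = 33.0,
        sub_perplexity: float | None = None,
        min_cluster_size: int = 5,
        min_samples: int = 13,
        tbx21_gene: str = "Tbx21",
        cck_gene: str = "Cck",
        glut_gene: str = "Slc17a7",
        expr_threshold: float = 3.0,
        tc2_frac_cutoff: float = 0.5,
        alpha: float = 0.05,
        inside_frac: float = 0.5,
        outside_frac: float = 0.1,
        tbx21_scope: str = "rich",
        random_state: int | None = 0,
    ):
        self.n_top_genes = n_top_genes
        self.n_bins = n_bins
        self.fano_on_log = fano_on_log
        self.n_pcs = n_pcs
        self.learning_rate = learning_rate
        self.perplexity = perplexity
        self.sub_perplexity = sub_perplexity
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.tbx21_gene = tbx21_gene
        self.cck_gene = cck_gene
        self.glut_gene = glut_gene
        self.expr_threshold = expr_threshold
        self.tc2_frac_cutoff = tc2_frac_cutoff
        self.alpha = alpha
        self.inside_frac = inside_frac
        self.outside_frac = outside_frac
        self.tbx21_scope = tbx21_scope
        self.random_state = random_state

    def fit(self, X, y=None, gene_names=None):
        if isinstance(X, pd.DataFrame):
            gene_names = X.columns.to_numpy(dtype=object)
            X = X.to_numpy()
        X = np.asarray(X)
        if gene_names is None:
            raise ValueError("gene_names are required (DataFrame columns or argument)")
        gene_names = np.asarray(gene_names, dtype=object)
        for g in (self.tbx21_gene, self.cck_gene, self.glut_gene):
            if g not in set(gene_names):
                raise ValueError(f"required marker gene {g!r} absent from the matrix")
        if self.n_top_genes > gene_names.size:
            raise ValueError("n_top_genes exceeds the number of genes")

        log_expr = log_transform(X.T)  # genes x cells
        self.log_expr_ = log_expr
        self.gene_names_ = gene_names

        selector = OverdispersedGeneSelector(
            n_top=self.n_top_genes, n_bins=self.n_bins, on_log=self.fano_on_log
        )
        selector.fit(pd.DataFrame(X, columns=gene_names))
        self.gene_stats_ = selector.gene_stats_
        self.selected_genes_ = selector.selected_genes_
        sel_idx = selector.support_
        logger.info("selected %d overdispersed genes", sel_idx.sum())

        Xsel = log_expr[sel_idx].T  # cells x selected genes
        embedder = TSNEEmbedder(self.n_pcs, self.learning_rate, self.perplexity,
                                self.random_state)
        self.embedding_ = embedder.fit_transform(Xsel)
        self.labels_ = DensityClusterer(self.min_cluster_size, self.min_samples).fit_predict(
            self.embedding_
        )
        whole = ClusterAssignment(labels=self.labels_)
        logger.info(
            "whole-dataset clustering: %d clusters, %d noise cells",
            len(whole.cluster_ids), int((self.labels_ == -1).sum()),
        )

        self.tbx21_cluster_ = find_marker_rich_cluster(
            whole, log_expr, gene_names, self.tbx21_gene
        )
        if self.tbx21_scope == "top":
            self.tbx21_clusters_ = [self.tbx21_cluster_]
        elif self.tbx21_scope == "rich":
            # union of clusters whose Tbx21-expressing fraction clears the
            # same threshold-3 rule; covers the case where the first pass has
            # already split the mitral and tufted populations
            self.tbx21_clusters_ = [
                c for c in whole.cluster_ids
                if marker_fraction(log_expr, gene_names, self.labels_ == c,
                                   self.tbx21_gene, self.expr_threshold) > 0.5
            ] or [self.tbx21_cluster_]
        else:
            raise ValueError("tbx21_scope must be 'rich' or 'top'")
        tbx_mask = np.isin(self.labels_, self.tbx21_clusters_)
        logger.info("Tbx21-rich clusters %s: %d cells", self.tbx21_clusters_, tbx_mask.sum())

        sub_perp = self.sub_perplexity
        if sub_perp is None:
            sub_perp = min(self.perplexity, max((tbx_mask.sum() - 1) / 3.0 - 1, 2.0))
        sub_embedder = TSNEEmbedder(self.n_pcs, self.learning_rate, sub_perp,
                                    self.random_state)
        self.sub_embedding_ = sub_embedder.fit_transform(Xsel[tbx_mask])
        self.sub_labels_ = DensityClusterer(self.min_cluster_size, self.min_samples).fit_predict(
            self.sub_embedding_
        )
        sub = ClusterAssignment(labels=self.sub_labels_)
        sub_log = log_expr[:, tbx_mask]
        assign_putative_mc(sub, sub_log, gene_names, self.cck_gene, self.expr_threshold)

        tc2_ids = define_tc2(
            whole, log_expr, gene_names, self.tbx21_clusters_,
            self.cck_gene, self.glut_gene, self.expr_threshold, self.tc2_frac_cutoff,
        )

        roles = np.full(X.shape[0], "other", dtype=object)
        roles[self.labels_ == -1] = "noise"
        roles[np.isin(self.labels_, tc2_ids)] = "TC2"
        tbx_idx = np.flatnonzero(tbx_mask)
        for c, role in sub.roles.items():
            roles[tbx_idx[self.sub_labels_ == c]] = role
        roles[tbx_idx[self.sub_labels_ == -1]] = "noise"
        self.roles_ = roles

        mc_mask = roles == "MC"
        comparison = [roles == "TC1"] + [
            (self.labels_ == c) for c in tc2_ids
        ]
        self.marker_table_ = screen_markers(
            log_expr, gene_names, mc_mask, comparison,
            alpha=self.alpha, expr_threshold=self.expr_threshold,
            inside_frac=self.inside_frac, outside_frac=self.outside_frac,
        )
        self.markers_ = list(self.marker_table_.index[self.marker_table_["marker"]])
        logger.info("screen passed %d marker genes: %s", len(self.markers_), self.markers_)
        return self

    def fit_matrix(self, matrix: ExpressionMatrix):
        """Fit from a genes x cells :class:`ExpressionMatrix`."""
        return self.fit(matrix.counts.T, gene_names=matrix.gene_names)

    def manifest(self) -> dict:
        """All parameters + version, sufficient to re-run the analysis."""
        return {
            "software": "obmark",
            "version": __version__,
            "params": self.get_params(),
        }


def run_markers(matrix_path: str | Path, outdir: str | Path, seed: int = 0,
                **params) -> MarkerDiscovery:
    """Read a matrix (loom or MTX triplet), run the pipeline, write outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = read_matrix(matrix_path)
    model = MarkerDiscovery(random_state=seed, **params).fit_matrix(matrix)

    pd.DataFrame(model.embedding_, columns=["tsne1", "tsne2"]).assign(
        cell=matrix.cell_ids, cluster=model.labels_, role=model.roles_
    ).to_csv(outdir / "embedding.csv", index=False)
    model.gene_stats_.to_csv(outdir / "gene_stats.csv")
    model.marker_table_.to_csv(outdir / "marker_table.csv")
    manifest = model.manifest()
    manifest["input"] = str(matrix_path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return model


def run_histology(scene_dir: str | Path, outdir: str | Path, n_bins: int = 20) -> dict:
    """Quantify a laminar scene: profiles, DPI, MCL fraction, densities."""
    from .histology import (
        dendritic_preference_index,
        depth_density_profile,
        linear_density,
        mcl_fraction,
        normalize_epl_depth,
    )
    from .io import read_scene

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene = read_scene(scene_dir)
    results: dict = {}

    depths, valid = normalize_epl_depth(scene.somata, scene, return_valid=True)
    pd.DataFrame({"x": scene.somata[:, 0], "y": scene.somata[:, 1],
                  "depth": depths, "valid": valid}).to_csv(
        outdir / "soma_depths.csv", index=False)
    if valid.any():
        results["mcl_fraction"] = mcl_fraction(depths[valid])
        prof = depth_density_profile(scene, source="points", n_bins=n_bins)
        prof.to_csv(outdir / "soma_depth_profile.csv", index=False)
    else:
        logger.warning("no valid somata in scene")
        results["mcl_fraction"] = float("nan")

    if scene.dendrite_mask is not None:
        prof = depth_density_profile(scene, source="mask", n_bins=n_bins)
        prof.to_csv(outdir / "dendrite_profile.csv", index=False)
        results["dpi"] = dendritic_preference_index(prof)

    if valid.any():
        try:
            dens = linear_density(scene)
        except ValueError as e:
            # open (non-ring) MCL sections have no polar standardization
            logger.info("skipping polar statistics: %s", e)
        else:
            dens.to_csv(outdir / "linear_density.csv", index=False)
            results["density_per_mm"] = float(
                dens.loc[dens["quadrant"] == "all", "density_per_mm"].iloc[0]
            )
    (outdir / "summary.json").write_text(json.dumps(results, indent=2))
    return results
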