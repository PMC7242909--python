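"""Dimensionality reduction, SNN community clustering and marker detection.

The workflow mirrors the standard Smart-seq2 analysis stack: highly variable
genes are selected by binned dispersion on the log matrix, cells are embedded
with PCA (10-30 components), a shared-nearest-neighbor (SNN) graph with
Jaccard edge weights is built in PC space, communities are found by
modularity optimization at a tunable resolution, and cluster markers are
ranked with a two-sided Wilcoxon rank-sum test.  Module scores (mean set
expression minus expression-matched controls) and ordinary least-squares
regression of a per-cell covariate out of the matrix support cell-cycle
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ModuleScoreSpec",
    "select_hvg",
    "pca_embed",
    "cluster_snn",
    "rank_markers_wilcoxon",
    "module_score",
    "regress_out",
    "merge_clusters",
    "run_clustering",
]


@dataclass
class ClusterAssignment:
    """Cell -> cluster-id map with the parameters that produced it.

    Cluster ids are contiguous integers from 0, ordered by decreasing size.
    """

    labels: pd.Series  # index = cell names, values = int cluster ids
    resolution: float = 0.8
    n_pcs: int = 20
    seed: int = 0

    def __post_init__(self):
        self.labels = self.labels.astype(int)
        ids = np.unique(self.labels.to_numpy())
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cells_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    @classmethod
    def from_array(cls, labels, cells, **kw) -> "ClusterAssignment":
        codes = pd.Series(labels, index=list(cells))
        # relabel to contiguous ids ordered by decreasing cluster size
        counts = codes.value_counts()
        order = counts.sort_values(ascending=False).index
        mapping = {old: new for new, old in enumerate(order)}
        return cls(codes.map(mapping), **kw)


@dataclass
class ModuleScoreSpec:
    """Gene-set score configuration: expression-bin-matched control sampling."""

    genes: list[str]
    n_bins: int = 25
    n_controls_per_gene: int = 50
    seed: int = 0


def select_hvg(matrix: ExpressionMatrix, n_top: int, n_bins: int = 20) -> list[str]:
    """Rank genes by binned normalized dispersion on log expression.

    Genes are binned by mean log expression; within each bin the dispersion
    (variance/mean) is z-scored, and the ``n_top`` genes with the highest
    standardized dispersion are returned.  Deterministic.
    """
    vals = matrix.values
    mean = vals.mean(axis=1)
    var = vals.var(axis=1)
    if not (var > 0).any():
        raise ValueError("no variable genes: all genes are constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    if n_top > matrix.n_genes:
        logger.warning("n_top=%d exceeds gene count %d; clamping",
                       n_top, matrix.n_genes)
        n_top = matrix.n_genes
    # keep bins populated enough for a meaningful within-bin z-score
    n_bins_eff = min(n_bins, max(1, matrix.n_genes // 5),
                     len(np.unique(mean)))
    bins = pd.qcut(mean, q=n_bins_eff, duplicates="drop", labels=False)
    disp_z = np.empty_like(disp)
    for b in np.unique(bins):
        m = bins == b
        mu, sd = disp[m].mean(), disp[m].std()
        disp_z[m] = (disp[m] - mu) / sd if sd > 0 else 0.0
    order = np.lexsort((matrix.genes, -disp_z))  # stable tie-break by name
    return [matrix.genes[i] for i in order[:n_top]]


def pca_embed(matrix: ExpressionMatrix, genes: list[str] | None = None,
              n_pcs: int = 20, scale: bool = True) -> pd.DataFrame:
    """Embed cells on the top principal components of the (scaled) log matrix.

    Input is centered per gene and, by default, scaled to unit variance.
    Component signs follow a fixed convention (the largest-magnitude gene
    loading of each component is positive) so embeddings are reproducible
    across runs and BLAS builds.
    """
    sub = matrix.subset_genes(genes) if genes is not None else matrix
    X = sub.values.T.copy()  # cells x genes
    X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
    max_rank = min(X.shape)
    if n_pcs > max_rank:
        logger.warning("n_pcs=%d exceeds rank %d; clamping", n_pcs, max_rank)
        n_pcs = max_rank
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest |loading| positive per component
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return pd.DataFrame(coords, index=sub.cells,
                        columns=[f"PC{j + 1}" for j in range(n_pcs)])


def snn_graph(embedding: pd.DataFrame, k_neighbors: int = 20,
              prune: float = 1.0 / 15.0) -> sparse.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighbor set is its ``k_neighbors`` nearest cells (Euclidean
    in PC space, the cell itself included); the weight of edge (i, j) is the
    Jaccard overlap of the two neighbor sets, pruned below ``prune``.
    """
    n = embedding.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} cells, "
                         f"got {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding.to_numpy())
    adj = nn.kneighbors_graph(mode="connectivity").tolil()
    adj.setdiag(1.0)  # cell belongs to its own neighbor set
    adj = adj.tocsr()
    shared = (adj @ adj.T).toarray()
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, shared / union, 0.0)
    np.fill_diagonal(jac, 0.0)
    jac[jac < prune] = 0.0
    return sparse.csr_matrix(jac)


def cluster_snn(embedding: pd.DataFrame, k_neighbors: int = 20,
                resolution: float = 0.8, seed: int = 0,
                prune: float = 1.0 / 15.0) -> ClusterAssignment:
    """SNN graph construction followed by modularity community detection.

    Communities are found with the Leiden algorithm on the Jaccard-weighted
    SNN graph using the resolution-parametrized modularity objective;
    deterministic given ``seed``.
    """
    snn = snn_graph(embedding, k_neighbors=k_neighbors, prune=prune)
    sources, targets = snn.nonzero()
    upper = sources < targets
    edges = list(zip(sources[upper].tolist(), targets[upper].tolist()))
    weights = np.asarray(snn[sources[upper], targets[upper]]).ravel().tolist()
    g = igraph.Graph(n=snn.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution, seed=seed,
        n_iterations=-1)
    return ClusterAssignment.from_array(
        np.array(part.membership), embedding.index,
        resolution=resolution, n_pcs=embedding.shape[1], seed=seed)


def rank_markers_wilcoxon(matrix: ExpressionMatrix,
                          assignment: ClusterAssignment, cluster: int,
                          adjust: str = "bonferroni",
                          pseudocount: float = 1.0) -> pd.DataFrame:
    """Rank genes distinguishing one cluster from all other cells.

    Per gene, a two-sided Wilcoxon rank-sum test (normal approximation with
    tie correction) compares in-cluster against out-of-cluster cells.  The
    log fold-change is the natural log of the ratio of group means on the
    linear scale (``expm1`` of the log matrix) with a pseudocount.  Rows are
    sorted by p-value, ties broken by |log fold-change|.

    Columns: gene, cluster, lfc, pct_in, pct_out, statistic, p, p_adj.
    """
    labels = assignment.labels.loc[matrix.cells].to_numpy()
    in_mask = labels == cluster
    if in_mask.sum() < 3:
        raise ValueError(f"cluster {cluster} has fewer than 3 cells")
    if (~in_mask).sum() < 1:
        raise ValueError("no out-of-cluster cells to compare against")
    vals = matrix.values
    x, y = vals[:, in_mask], vals[:, ~in_mask]

    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided",
                                     method="asymptotic")
    p = np.where(np.isnan(p), 1.0, p)  # fully tied genes carry no evidence
    lin_x, lin_y = np.expm1(x), np.expm1(y)
    lfc = np.log((lin_x.mean(axis=1) + pseudocount)
                 / (lin_y.mean(axis=1) + pseudocount))
    pct_in = (x > 0).mean(axis=1)
    pct_out = (y > 0).mean(axis=1)

    n = matrix.n_genes
    if adjust == "bonferroni":
        p_adj = np.minimum(p * n, 1.0)
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    res = pd.DataFrame(
        {"gene": matrix.genes, "cluster": cluster, "lfc": lfc,
         "pct_in": pct_in, "pct_out": pct_out, "statistic": stat,
         "p": p, "p_adj": p_adj})
    res["_abs_lfc"] = -res["lfc"].abs()
    res = res.sort_values(["p", "_abs_lfc", "gene"]).drop(columns="_abs_lfc")
    return res.reset_index(drop=True)


def module_score(matrix: ExpressionMatrix, spec: ModuleScoreSpec) -> pd.Series:
    """Gene-set activity score per cell.

    The score is the mean expression of the set minus the mean of control
    genes drawn, for every set gene, from the same average-expression bin
    (``n_bins`` equal-frequency bins over all genes; ``n_controls_per_gene``
    controls per set gene, sampled without replacement where possible,
    seeded).  Centered near zero when the set carries no signal.
    """
    set_genes = [g for g in dict.fromkeys(spec.genes) if g in matrix.genes]
    if not set_genes:
        raise ValueError("gene set does not intersect matrix genes")
    mean_expr = matrix.data.mean(axis=1)
    n_bins = min(spec.n_bins, max(1, mean_expr.nunique()))
    bins = pd.qcut(mean_expr.rank(method="first"), q=n_bins, labels=False)
    rng = np.random.default_rng(spec.seed)
    controls: list[str] = []
    for g in set_genes:
        pool = bins.index[(bins == bins[g]) & (bins.index != g)]
        if len(pool) == 0:
            pool = bins.index[bins.index != g]
        size = min(spec.n_controls_per_gene, len(pool))
        controls.extend(rng.choice(pool, size=size, replace=False))
    set_mean = matrix.data.loc[set_genes].mean(axis=0)
    ctrl_mean = matrix.data.loc[controls].mean(axis=0)
    return (set_mean - ctrl_mean).rename("module_score")


def regress_out(matrix: ExpressionMatrix, covariate) -> ExpressionMatrix:
    """Remove a per-cell covariate from every gene by ordinary least squares.

    Each gene's expression is replaced by the residual of its OLS regression
    on the covariate, with the gene mean added back to keep the original
    scale; residuals may dip below zero, as in standard covariate-corrected
    expression matrices.  A constant covariate leaves the matrix unchanged
    (with a warning).
    """
    cov = np.asarray(pd.Series(covariate).loc[matrix.cells]
                     if isinstance(covariate, pd.Series) else covariate,
                     dtype=float)
    if cov.shape[0] != matrix.n_cells:
        raise ValueError("covariate length must match cell count")
    if not np.isfinite(cov).all():
        raise ValueError("covariate must be finite")
    c = cov - cov.mean()
    denom = (c ** 2).sum()
    if denom == 0:
        logger.warning("constant covariate: matrix returned unchanged")
        return matrix.copy()
    vals = matrix.values
    gene_means = vals.mean(axis=1, keepdims=True)
    centered = vals - gene_means
    beta = centered @ c / denom  # per-gene slope
    resid = centered - beta[:, None] * c[None, :] + gene_means
    return ExpressionMatrix(resid, genes=list(matrix.genes),
                            cells=list(matrix.cells), allow_negative=True)


def merge_clusters(assignment: ClusterAssignment,
                   merge: list[int]) -> ClusterAssignment:
    """Merge the given cluster ids into one and relabel contiguously.

    Supports the manual curation step of collapsing clusters judged to be the
    same cell type; the judgment itself is the analyst's.
    """
    if len(merge) < 2:
        raise ValueError("need at least two clusters to merge")
    target = min(merge)
    labels = assignment.labels.copy()
    labels[labels.isin(merge)] = target
    return ClusterAssignment.from_array(
        labels.to_numpy(), labels.index, resolution=assignment.resolution,
        n_pcs=assignment.n_pcs, seed=assignment.seed)


def run_clustering(matrix: ExpressionMatrix, n_hvg: int = 200,
                   n_pcs: int = 20, k_neighbors: int = 20,
                   resolution: float = 0.8, seed: int = 0) -> ClusterAssignment:
    """HVG selection -> PCA -> SNN Leiden clustering in one call."""
    hvg = select_hvg(matrix, n_hvg)
    emb = pca_embed(matrix, hvg, n_pcs=n_pcs)
    return cluster_snn(emb, k_neighbors=k_neighbors, resolution=resolution,
                       seed=seed)
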