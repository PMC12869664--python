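"""Single-cell core: QC, log-normalization, graph clustering, pseudobulk
centroids and simplified nearest-centroid cell-type annotation.

Clustering follows the standard scRNA-seq recipe: PCA on log-normalized
expression, a k-nearest-neighbor graph over the top components, and Louvain
community detection (igraph's multilevel algorithm) with a resolution
parameter, default 2.5.  Cell-type annotation is a rank-based (Spearman)
nearest-centroid match against a reference table, a deliberately simple
stand-in for reference-database classifiers such as SingleR.
"""

from __future__ import annotations

import logging
import random

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .containers import (CellCohort, ClusterAssignment, NormalizedMatrix,
                         PseudobulkProfile)

log = logging.getLogger(__name__)


def qc_filter(
    cohort: CellCohort,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Detected-gene QC: returns (cell_mask, gene_mask).

    A cell passes iff it expresses at least ``min_genes_per_cell`` genes; a
    gene is kept iff detected in at least ``min_cells_per_gene`` cells.  The
    masks are computed on the raw matrix, so applying them twice is a no-op.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    detected = cohort.counts > 0
    genes_per_cell = np.asarray(detected.sum(axis=0)).ravel()
    cells_per_gene = np.asarray(detected.sum(axis=1)).ravel()
    cell_mask = genes_per_cell >= min_genes_per_cell
    gene_mask = cells_per_gene >= min_cells_per_gene
    if not cell_mask.any():
        raise ValueError(
            f"all {cohort.n_cells} cells fail QC at min_genes_per_cell="
            f"{min_genes_per_cell}; lower the threshold"
        )
    return cell_mask, gene_mask


def log_normalize(cohort: CellCohort, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Library-size log-normalization: log1p(count / total * scale_factor)."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(cohort.counts.sum(axis=0)).ravel().astype(float)
    if (totals[cohort.qc_pass] == 0).any():
        raise ValueError("QC-passing cell with zero total count")
    totals[totals == 0] = 1.0  # only affects cells already failing QC
    values = cohort.counts.tocsc(copy=True).astype(float)
    values = values.multiply(sp.csr_matrix(scale_factor / totals)).tocsr()
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=values, scale_factor=float(scale_factor),
        gene_ids=cohort.gene_ids, cell_ids=cohort.cell_ids,
    )


def cluster_cells(
    norm: NormalizedMatrix,
    resolution: float = 2.5,
    n_neighbors: int = 20,
    n_pcs: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """Louvain clustering on a kNN graph over top principal components.

    Deterministic given ``seed``; cluster ids are relabeled contiguously in
    decreasing size order.
    """
    n_cells = norm.n_cells
    if n_cells < n_neighbors + 1:
        raise ValueError(
            f"{n_cells} cells is fewer than n_neighbors+1={n_neighbors + 1}"
        )
    X = np.asarray(norm.values.T.todense())
    n_comp = min(n_pcs, n_cells - 1, norm.n_genes - 1)
    pcs = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=seed).fit_transform(X)
    knn = kneighbors_graph(pcs, n_neighbors=n_neighbors, mode="connectivity")
    adj = knn.maximum(knn.T).tocoo()  # symmetrize: union of neighborhoods
    edges = [(i, j) for i, j in zip(adj.row, adj.col) if i < j]
    g = igraph.Graph(n=n_cells, edges=edges)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    labels = np.asarray(part.membership)
    # contiguous ids, largest cluster first (stable tie-break on old id)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[v] for v in labels])
    return ClusterAssignment(labels=labels, cell_ids=norm.cell_ids,
                             resolution=float(resolution))


def pseudobulk_centroids(
    norm: NormalizedMatrix,
    assign: ClusterAssignment,
    cell_meta: pd.DataFrame | None = None,
) -> list[PseudobulkProfile]:
    """Mean log-normalized expression per cluster, with sample composition."""
    if len(assign.labels) != norm.n_cells:
        raise ValueError("assignment does not cover the normalized matrix")
    profiles = []
    for cid in range(assign.n_clusters):
        mask = assign.labels == cid
        n = int(mask.sum())
        if n == 0:
            log.warning("cluster %d is empty; skipped", cid)
            continue
        centroid = np.asarray(norm.values[:, mask].mean(axis=1)).ravel()
        comp = {}
        if cell_meta is not None:
            comp = cell_meta.loc[mask, "sample_id"].value_counts().to_dict()
        profiles.append(PseudobulkProfile(
            cluster_id=cid, centroid=centroid, n_cells=n,
            composition=comp, gene_ids=norm.gene_ids,
        ))
    return profiles


def annotate_cell_types(
    profiles: list[PseudobulkProfile],
    reference: pd.DataFrame,
    min_shared_genes: int = 20,
) -> pd.DataFrame:
    """Label each cluster by its best Spearman match in a reference table.

    ``reference`` is genes x cell-types.  Ties go to the first type in
    reference column order (logged).
    """
    out = []
    for prof in profiles:
        shared = pd.Index(prof.gene_ids).intersection(reference.index)
        if len(shared) < min_shared_genes:
            raise ValueError(
                f"only {len(shared)} genes shared with reference "
                f"(need >= {min_shared_genes})"
            )
        cvec = pd.Series(prof.centroid, index=prof.gene_ids).loc[shared]
        scores = {}
        for ct in reference.columns:
            rho = stats.spearmanr(cvec.to_numpy(),
                                  reference.loc[shared, ct].to_numpy()).statistic
            scores[ct] = rho
        s = pd.Series(scores)
        best = s.idxmax()  # first column wins ties (pandas keeps order)
        if (s == s.max()).sum() > 1:
            log.info("cluster %d: annotation tie broken toward %s",
                     prof.cluster_id, best)
        out.append({"cluster_id": prof.cluster_id, "cell_type": best,
                    "score": s[best]})
    return pd.DataFrame(out).set_index("cluster_id")
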