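"""Core in-memory containers shared across the pipeline.

Orientation convention: expression matrices are genes x cells (rows are
genes), matching the Matrix Market layout used on disk.  Cell metadata is a
pandas DataFrame indexed by cell barcode.  Hidden simulation truth (true
subclone of each cell, planted low-depth flags) lives in a separate
``truth`` frame so that analysis code can never accidentally consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

TIMEPOINTS = ("diagnosis", "relapse", "normal", "treated", "control")


@dataclass
class CellCohort:
    """Sparse gene x cell counts plus per-cell metadata.

    ``cell_meta`` must carry at least ``patient``, ``sample_id`` and
    ``timepoint`` columns; ``qc_pass`` marks cells surviving QC (all True
    until :func:`clonerisk.sc.qc_filter` is applied).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    qc_pass: np.ndarray = None
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.qc_pass is None:
            self.qc_pass = np.ones(self.n_cells, dtype=bool)
        self.qc_pass = np.asarray(self.qc_pass, dtype=bool)
        if self.counts.shape != (self.n_genes, self.n_cells):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.n_genes} genes x {self.n_cells} cells"
            )
        if len(set(self.gene_ids)) != self.n_genes:
            raise ValueError("gene_ids must be unique")
        if len(self.cell_meta) != self.n_cells:
            raise ValueError("cell_meta rows must match number of cells")
        for col in ("patient", "sample_id", "timepoint"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def filtered(self, cell_mask: np.ndarray, gene_mask: np.ndarray | None = None) -> "CellCohort":
        """Subset to the given cells (and optionally genes)."""
        if gene_mask is None:
            gene_mask = np.ones(self.n_genes, dtype=bool)
        counts = self.counts[gene_mask][:, cell_mask]
        return CellCohort(
            counts=counts,
            gene_ids=self.gene_ids[gene_mask],
            cell_ids=self.cell_ids[cell_mask],
            cell_meta=self.cell_meta.loc[cell_mask].copy(),
            qc_pass=self.qc_pass[cell_mask],
            truth=None if self.truth is None else self.truth.loc[cell_mask].copy(),
        )


def concat_cohorts(cohorts: list[CellCohort]) -> CellCohort:
    """Concatenate cohorts sharing the same gene universe (column-wise)."""
    ref = cohorts[0]
    for c in cohorts[1:]:
        if not np.array_equal(c.gene_ids, ref.gene_ids):
            raise ValueError("cohorts must share an identical gene universe")
    truth = None
    if all(c.truth is not None for c in cohorts):
        truth = pd.concat([c.truth for c in cohorts], axis=0)
    return CellCohort(
        counts=sp.hstack([c.counts for c in cohorts], format="csr"),
        gene_ids=ref.gene_ids,
        cell_ids=np.concatenate([c.cell_ids for c in cohorts]),
        cell_meta=pd.concat([c.cell_meta for c in cohorts], axis=0),
        qc_pass=np.concatenate([c.qc_pass for c in cohorts]),
        truth=truth,
    )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells, log1p(count/total * scale)."""

    values: sp.csr_matrix
    scale_factor: float
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClusterAssignment:
    """Cluster label per cell (contiguous ids from 0)."""

    labels: np.ndarray
    cell_ids: np.ndarray
    resolution: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class PseudobulkProfile:
    """Mean log-normalized expression of one cluster."""

    cluster_id: int
    centroid: np.ndarray
    n_cells: int
    composition: dict = field(default_factory=dict)  # sample_id -> cell count
    gene_ids: np.ndarray | None = None


@dataclass(frozen=True)
class MergeConfig:
    """Cluster-merging parameters: correlation threshold and minimum size."""

    r_threshold: float = 0.986
    min_cells: int = 50

    def __post_init__(self):
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in (0, 1)")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")


@dataclass
class MergedSubclone:
    """A merged cluster group: the unit the signature matrix is built from."""

    subclone_id: str
    centroid: np.ndarray  # log-normalized scale, cell-count-weighted mean
    n_cells: int
    members: list  # (patient, cluster_id) provenance
    labels: list = field(default_factory=list)  # longitudinal labels of members
    gene_ids: np.ndarray | None = None


@dataclass
class SignatureMatrix:
    """Gene x merged-subclone reference on the linear expression scale."""

    matrix: pd.DataFrame  # genes x subclones
    provenance: dict  # subclone_id -> {members, labels, n_cells}

    def __post_init__(self):
        if (self.matrix.to_numpy().sum(axis=0) == 0).any():
            raise ValueError("signature matrix has an all-zero column")
        for sid in self.matrix.columns:
            if not self.provenance.get(sid, {}).get("members"):
                raise ValueError(f"subclone {sid} has empty provenance")

    @property
    def subclone_ids(self):
        return list(self.matrix.columns)


@dataclass
class AbundanceEstimate:
    """Non-negative per-subclone proportions for one bulk sample (sum 1)."""

    proportions: pd.Series
    residual_norm: float
    kkt_residual: float
    method: str

    def __post_init__(self):
        v = self.proportions.to_numpy(dtype=float)
        if (v < -1e-12).any():
            raise ValueError("abundances must be non-negative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
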