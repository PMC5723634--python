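"""Core data containers shared across the pipeline.

The universal input is a :class:`CountMatrix`: a cells x genes matrix of UMI
counts with per-cell sample/time-point annotations. Downstream stages produce
structured results (QC reports, normalised matrices, cluster assignments,
diffusion embeddings, trend tables) that are thin wrappers around pandas /
numpy objects so they serialise naturally to TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its documented contract."""


@dataclass
class CountMatrix:
    """UMI count matrix (cells x genes) with cell and gene annotations.

    Counts are stored as a CSR sparse matrix of non-negative integers.
    ``cell_ids`` are unique (barcode plus sample suffix); ``raw_barcodes``
    hold the bare droplet barcode used for cross-sample barcode checks.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    raw_barcodes: np.ndarray
    gene_ids: np.ndarray
    sample_of_cell: np.ndarray
    timepoint_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        for name in ("cell_ids", "raw_barcodes", "gene_ids",
                     "sample_of_cell", "timepoint_of_cell"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.raw_barcodes) != n_cells:
            raise ValueError(
                f"cell annotation length mismatch: matrix has {n_cells} cells")
        if len(self.sample_of_cell) != n_cells or len(self.timepoint_of_cell) != n_cells:
            raise ValueError("sample/timepoint annotation length mismatch")
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene annotation length mismatch: matrix has {n_genes} genes")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def samples(self) -> list:
        """Sample labels in order of first appearance."""
        return list(pd.unique(self.sample_of_cell))

    def subset_cells(self, index) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given cell index/mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[index],
            cell_ids=self.cell_ids[index],
            raw_barcodes=self.raw_barcodes[index],
            gene_ids=self.gene_ids,
            sample_of_cell=self.sample_of_cell[index],
            timepoint_of_cell=self.timepoint_of_cell[index],
        )

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class QCReport:
    """Per-cell QC metrics, per-sample adaptive thresholds and pass flags.

    ``cells`` columns: total_umis, genes_detected, mito_fraction, pass,
    reasons (comma-joined subset of {low_genes, low_umi, high_mito,
    shared_barcode}). ``sample_thresholds`` columns: gene_threshold,
    umi_threshold, indexed by sample.
    """

    cells: pd.DataFrame
    sample_thresholds: Optional[pd.DataFrame] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "pass" in self.cells.columns and "reasons" in self.cells.columns:
            ok = self.cells["pass"] == (self.cells["reasons"] == "")
            if not ok.all():
                raise ValueError("pass flag inconsistent with reason codes")


@dataclass
class NormalizedMatrix:
    """Size-factor-normalised log2 expression.

    ``logexpr[c, g] = log2(count[c, g] / size_factor[c] + 1)`` held dense;
    size factors are strictly positive with mean 1 across cells.
    """

    logexpr: np.ndarray
    size_factors: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    sample_of_cell: np.ndarray
    timepoint_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.logexpr = np.asarray(self.logexpr, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.logexpr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.logexpr.shape[1]


@dataclass
class ClusterAssignment:
    """Labels from the two-step clustering plus per-cluster flags.

    ``cells`` columns: coarse, refined, final (strings). ``cluster_info``
    is indexed by final cluster label with contaminant/doublet flags and
    per-sample cell counts. ``merge_history`` records (cluster_a, cluster_b,
    n_de, merged_into) tuples in merge order.
    """

    cells: pd.DataFrame
    cluster_info: pd.DataFrame = field(default_factory=pd.DataFrame)
    merge_history: list = field(default_factory=list)

    @property
    def final(self) -> np.ndarray:
        return self.cells["final"].to_numpy()


@dataclass
class DiffusionEmbedding:
    """Eigen-system of the density-normalised diffusion operator.

    ``components[:, i]`` is the (i+2)-th right eigenvector psi_{i+2} of the
    transition operator (the trivial constant eigenvector is dropped);
    ``eigenvalues[i]`` the matching eigenvalue, sorted decreasing.
    Reference kernel state (data, sigma, knn, density terms) is retained so
    held-out cells can be projected by the Nystroem extension.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    cell_ids: np.ndarray
    ref_data: np.ndarray
    sigma: float
    knn: int
    density_q: np.ndarray
    row_degree: np.ndarray
    ref_kth_dist: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(np.abs(self.eigenvalues) >= 1.0):
            raise ValueError("retained eigenvalues must satisfy |lambda| < 1")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted in decreasing order")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class TrajectoryAssignment:
    """Root/tips, diffusion pseudotime and two-branch labels."""

    root: str
    tip1: str
    tip2: str
    cells: pd.DataFrame  # index cell_id; pseudotime, branch, e_branch1, e_branch2

    def __post_init__(self) -> None:
        pt = self.cells.loc[self.root, "pseudotime"]
        if abs(pt) > 1e-9:
            raise ValueError("pseudotime at the root must be zero")

    @property
    def pseudotime(self) -> pd.Series:
        return self.cells["pseudotime"]

    @property
    def branch(self) -> pd.Series:
        return self.cells["branch"]


@dataclass
class TrendTable:
    """Spline fits along pseudotime, per gene and branch.

    ``per_branch`` rows are (gene, branch) with LRT statistics, amplitudes
    and gradients in {-1, 0, +1}; ``per_gene`` carries the shared /
    branch-specific / none classification; ``grids`` maps branch ->
    genes x 101 fitted-value matrix (DataFrame indexed by gene).
    """

    per_branch: pd.DataFrame
    per_gene: pd.DataFrame
    grids: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
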