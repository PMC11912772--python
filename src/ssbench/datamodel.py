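"""Core containers for spot-resolved expression data.

Everything downstream of I/O speaks these types: a gene x spot count matrix
with 2D spot coordinates (:class:`SpatialDataset`), a symmetric spot
adjacency (:class:`NeighborGraph`), a labelled single-cell reference
(:class:`SingleCellReference`) and a named sample of per-spot / per-gene
values (:class:`MetricSample`) — the unit the two-sample density comparison
consumes.

Orientation is fixed as genes x spots throughout; readers transpose as
needed.  Coordinates are continuous 2D and their units are never
interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


class DimensionMismatchError(ValidationError):
    """Raised when two inputs disagree on a shared cardinality."""


def _as_count_matrix(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise ValidationError(f"count matrix must be 2D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("count matrix must be numeric")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("count matrix contains non-finite entries")
    if (arr < 0).any():
        raise ValidationError("count matrix contains negative entries")
    return arr


@dataclass
class SpatialDataset:
    """Gene x spot UMI counts with spot coordinates and optional annotation.

    Parameters
    ----------
    counts
        Non-negative matrix, shape ``(n_genes, n_spots)``.
    gene_ids, spot_ids
        Unique string identifiers for rows / columns.
    coords
        Spot coordinates, shape ``(n_spots, 2)``; arbitrary spatial units.
    domains
        Optional per-spot spatial-domain label (length ``n_spots``).
    proportions
        Optional spots x cell-types matrix; each row sums to 1.
    """

    counts: np.ndarray
    gene_ids: list
    spot_ids: list
    coords: np.ndarray
    domains: Optional[np.ndarray] = None
    proportions: Optional[pd.DataFrame] = None
    name: str = "dataset"

    def __post_init__(self):
        self.counts = _as_count_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise DimensionMismatchError(
                f"{len(self.gene_ids)} gene ids vs {n_genes} count rows"
            )
        if len(self.spot_ids) != n_spots:
            raise DimensionMismatchError(
                f"{len(self.spot_ids)} spot ids vs {n_spots} count columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene_ids")
        if len(set(self.spot_ids)) != n_spots:
            raise ValidationError("duplicate spot_ids")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n_spots, 2):
            raise DimensionMismatchError(
                f"coords shape {self.coords.shape} vs {n_spots} spots x 2"
            )
        if self.domains is not None:
            self.domains = np.asarray(self.domains)
            if self.domains.shape != (n_spots,):
                raise DimensionMismatchError(
                    f"{self.domains.shape[0]} domain labels vs {n_spots} spots"
                )
        if self.proportions is not None:
            props = self.proportions
            if not isinstance(props, pd.DataFrame):
                props = pd.DataFrame(
                    np.asarray(props, dtype=float), index=self.spot_ids
                )
            if props.shape[0] != n_spots:
                raise DimensionMismatchError(
                    f"{props.shape[0]} proportion rows vs {n_spots} spots"
                )
            vals = props.to_numpy(dtype=float)
            if (vals < -1e-12).any():
                raise ValidationError("negative cell-type proportions")
            rowsum = vals.sum(axis=1)
            if np.abs(rowsum - 1.0).max() > 1e-8:
                raise ValidationError("proportion rows must sum to 1 (+-1e-8)")
            self.proportions = props

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Per-spot total UMI count N_k."""
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: Sequence[str]) -> "SpatialDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return replace(
            self, counts=self.counts[rows, :], gene_ids=list(gene_ids)
        )

    def subset_spots(self, spot_idx: np.ndarray) -> "SpatialDataset":
        spot_idx = np.asarray(spot_idx)
        return replace(
            self,
            counts=self.counts[:, spot_idx],
            spot_ids=[self.spot_ids[i] for i in spot_idx],
            coords=self.coords[spot_idx],
            domains=None if self.domains is None else self.domains[spot_idx],
            proportions=None
            if self.proportions is None
            else self.proportions.iloc[spot_idx],
        )

    def with_counts(self, counts: np.ndarray, name: Optional[str] = None) -> "SpatialDataset":
        """Copy of the dataset with counts replaced (same spots/genes/coords)."""
        counts = _as_count_matrix(counts)
        if counts.shape != self.counts.shape:
            raise DimensionMismatchError(
                f"replacement counts {counts.shape} vs {self.counts.shape}"
            )
        return replace(self, counts=counts, name=name or self.name)


@dataclass
class SingleCellReference:
    """Gene x cell count matrix with a cell-type label per cell."""

    counts: np.ndarray
    gene_ids: list
    cell_ids: list
    cell_types: np.ndarray

    def __post_init__(self):
        self.counts = _as_count_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise DimensionMismatchError(
                f"{len(self.gene_ids)} gene ids vs {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise DimensionMismatchError(
                f"{len(self.cell_ids)} cell ids vs {n_cells} columns"
            )
        self.cell_types = np.asarray(self.cell_types)
        if self.cell_types.shape != (n_cells,):
            raise DimensionMismatchError(
                f"{self.cell_types.shape[0]} labels vs {n_cells} cells"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class NeighborGraph:
    """Symmetric spot adjacency w_ij with zero diagonal.

    ``total_weight`` is W = sum_ij w_ij over ordered pairs, the normalizer
    of Moran's I.
    """

    adjacency: sp.csr_matrix
    k_param: Optional[int] = None
    method: str = "knn"

    def __post_init__(self):
        adj = sp.csr_matrix(self.adjacency, dtype=float)
        n = adj.shape[0]
        if adj.shape[0] != adj.shape[1]:
            raise ValidationError("adjacency must be square")
        if adj.diagonal().any():
            raise ValidationError("adjacency diagonal must be zero")
        if (abs(adj - adj.T)).sum() > 1e-12:
            raise ValidationError("adjacency must be symmetric")
        if n >= 2 and adj.sum() <= 0:
            raise ValidationError("graph has no edges (W must be > 0)")
        self.adjacency = adj

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.adjacency.sum())

    def edge_array(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Ordered neighbor pairs (i, j, w_ij) with w_ij > 0, i != j."""
        coo = self.adjacency.tocoo()
        return coo.row, coo.col, coo.data

    def degrees(self) -> np.ndarray:
        return np.asarray((self.adjacency > 0).sum(axis=1)).ravel()

    def to_networkx(self):
        import networkx as nx

        return nx.from_scipy_sparse_array(self.adjacency)


@dataclass
class MetricSample:
    """Named sample of per-spot or per-gene values for one metric.

    ``values`` is a 1D vector, or an ``(n, 2)`` array for relationship
    metrics.  Degenerate entries (NaN after computation) are dropped by the
    producing operation and counted in ``n_dropped``.
    """

    name: str
    level: str  # one of {"spot", "gene", "spatial"}
    values: np.ndarray
    source: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("spot", "gene", "spatial"):
            raise ValidationError(f"unknown metric level {self.level!r}")
        if self.values.ndim not in (1, 2):
            raise ValidationError("metric values must be 1D or paired 2D")
        if self.values.ndim == 2 and self.values.shape[1] != 2:
            raise ValidationError("paired metric values must have 2 columns")
        if np.isnan(self.values).any():
            raise ValidationError(
                f"metric {self.name!r} contains NaN after computation"
            )

    @property
    def dim(self) -> int:
        return 1 if self.values.ndim == 1 else 2

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class MomentSummary:
    """Per-axis means/variances of log2-CPM and their z-scored versions."""

    axis: str  # "spot" or "gene"
    means: np.ndarray
    variances: np.ndarray
    scaled_means: np.ndarray
    scaled_variances: np.ndarray
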