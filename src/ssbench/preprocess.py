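"""Preprocessing: log2-CPM normalization, single-cell QC, gene selection.

The QC rule retains cells with 200-2500 detected features and at most 5%
mitochondrial counts.  Gene selection keeps the top 1000 spatially variable
genes (ranked by Moran's I on log2-CPM) when a dataset has more; smaller
datasets pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    NeighborGraph,
    SingleCellReference,
    SpatialDataset,
    ValidationError,
)

log = logging.getLogger(__name__)


def log2cpm(
    counts: np.ndarray,
    pseudocount: float = 1.0,
    spot_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """log2(1e6 * Y_gk / N_k + pseudocount) with N_k the column sum.

    Raises if any column (spot) has zero library size, listing the
    offenders.
    """
    counts = np.asarray(counts, dtype=float)
    libs = counts.sum(axis=0)
    bad = np.nonzero(libs <= 0)[0]
    if bad.size:
        names = (
            [spot_ids[i] for i in bad] if spot_ids is not None else bad.tolist()
        )
        raise ValidationError(f"zero library size for spots: {names}")
    return np.log2(1e6 * counts / libs + pseudocount)


def dataset_log2cpm(ds: SpatialDataset, pseudocount: float = 1.0) -> np.ndarray:
    return log2cpm(ds.counts, pseudocount=pseudocount, spot_ids=ds.spot_ids)


def qc_filter_cells(
    ref: SingleCellReference, mito_gene_prefix: str = "MT-"
) -> tuple[SingleCellReference, dict]:
    """Filter cells by detected-feature count and mitochondrial fraction.

    Retains exactly the cells with 200 <= detected features <= 2500 and a
    mitochondrial count fraction <= 5%.  Returns the filtered reference and
    a per-criterion removal tally.
    """
    detected = (ref.counts > 0).sum(axis=0)
    mito_rows = np.array(
        [g.startswith(mito_gene_prefix) for g in ref.gene_ids], dtype=bool
    )
    totals = ref.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, ref.counts[mito_rows, :].sum(axis=0) / totals, 0.0
        )
    low = detected < 200
    high = detected > 2500
    mito = mito_frac > 0.05
    keep = ~(low | high | mito)
    tally = {
        "low_features": int(low.sum()),
        "high_features": int(high.sum()),
        "high_mito": int(mito.sum()),
        "retained": int(keep.sum()),
    }
    if not keep.any():
        raise ValidationError(
            "QC removed every cell; review thresholds "
            f"(tally: {tally})"
        )
    idx = np.nonzero(keep)[0]
    out = SingleCellReference(
        counts=ref.counts[:, idx],
        gene_ids=list(ref.gene_ids),
        cell_ids=[ref.cell_ids[i] for i in idx],
        cell_types=ref.cell_types[idx],
    )
    log.info("QC retained %d/%d cells (%s)", keep.sum(), ref.n_cells, tally)
    return out, tally


def select_genes(
    ds: SpatialDataset, graph: NeighborGraph, max_genes: int = 1000
) -> SpatialDataset:
    """Keep the ``max_genes`` most spatially variable genes.

    Genes are ranked by univariate Moran's I on log2-CPM (descending; ties
    broken by lexicographic gene id) and the original relative gene order
    is preserved in the output.  Datasets at or below the cap are returned
    unchanged, so the operation is idempotent.
    """
    if graph.n_spots != ds.n_spots:
        raise ValidationError(
            f"graph has {graph.n_spots} spots, dataset has {ds.n_spots}"
        )
    if ds.n_genes <= max_genes:
        return ds
    from .spatial_metrics import morans_i_genes

    expr = dataset_log2cpm(ds)
    scores = morans_i_genes(expr, graph)
    order = sorted(
        range(ds.n_genes), key=lambda i: (-scores[i], ds.gene_ids[i])
    )
    keep = sorted(order[:max_genes])  # preserve original relative order
    return replace(
        ds,
        counts=ds.counts[keep, :],
        gene_ids=[ds.gene_ids[i] for i in keep],
    )
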