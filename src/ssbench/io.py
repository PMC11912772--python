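"""Readers and writers for the on-disk dataset layout.

A dataset directory uses the 10x-style triplet layout: ``matrix.mtx``
(Matrix Market, genes x spots), ``features.tsv`` (one gene id per line),
``barcodes.tsv`` (one spot id per line; barcode order defines spot order),
plus ``coords.csv`` with columns ``spot_id,x,y`` and optional
``domains.csv`` (``spot_id,domain``) and ``proportions.csv``
(``spot_id,<type1>,<type2>,...``).  All tables round-trip losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datamodel import (
    DimensionMismatchError,
    SingleCellReference,
    SpatialDataset,
    ValidationError,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _read_id_column(path: PathLike) -> list:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return ids


def read_spatial_dataset(
    matrix_path: PathLike,
    features_path: PathLike,
    barcodes_path: PathLike,
    coords_path: PathLike,
    domains_path: Optional[PathLike] = None,
    proportions_path: Optional[PathLike] = None,
    name: Optional[str] = None,
) -> SpatialDataset:
    """Read a dataset directory's component files into a :class:`SpatialDataset`.

    Matrix orientation is normalized to genes x spots using the feature and
    barcode cardinalities; any mismatch between the matrix, the id files and
    the coordinate table raises rather than truncates.
    """
    genes = _read_id_column(features_path)
    spots = _read_id_column(barcodes_path)
    if len(set(spots)) != len(spots):
        raise ValidationError(f"duplicate spot ids in {barcodes_path}")

    mat = sio.mmread(str(matrix_path))
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if mat.shape == (len(genes), len(spots)):
        pass
    elif mat.shape == (len(spots), len(genes)) and len(genes) != len(spots):
        mat = mat.T
    else:
        raise DimensionMismatchError(
            f"matrix shape {mat.shape} does not match {len(genes)} features "
            f"x {len(spots)} barcodes"
        )

    coords_df = pd.read_csv(coords_path, float_precision="round_trip")
    required = {"spot_id", "x", "y"}
    if not required.issubset(coords_df.columns):
        raise ValidationError(
            f"coords CSV must have columns spot_id,x,y; got {list(coords_df.columns)}"
        )
    coords_df["spot_id"] = coords_df["spot_id"].astype(str)
    coords_df = coords_df.set_index("spot_id")
    missing = [s for s in spots if s not in coords_df.index]
    extra = [s for s in coords_df.index if s not in set(spots)]
    if missing or extra:
        raise DimensionMismatchError(
            f"coords/barcode mismatch: {len(missing)} barcodes lack coordinates, "
            f"{len(extra)} coordinate rows lack barcodes "
            f"({len(coords_df)} coords vs {len(spots)} barcodes)"
        )
    coords = coords_df.loc[spots, ["x", "y"]].to_numpy(dtype=float)

    domains = None
    if domains_path is not None:
        dom_df = pd.read_csv(domains_path)
        dom_df["spot_id"] = dom_df["spot_id"].astype(str)
        dom_df = dom_df.set_index("spot_id")
        if set(dom_df.index) != set(spots):
            raise DimensionMismatchError(
                f"domain labels cover {len(dom_df)} spots, dataset has {len(spots)}"
            )
        domains = dom_df.loc[spots, "domain"].to_numpy()

    proportions = None
    if proportions_path is not None:
        prop_df = pd.read_csv(proportions_path, float_precision="round_trip")
        prop_df["spot_id"] = prop_df["spot_id"].astype(str)
        prop_df = prop_df.set_index("spot_id")
        if set(prop_df.index) != set(spots):
            raise DimensionMismatchError(
                f"proportions cover {len(prop_df)} spots, dataset has {len(spots)}"
            )
        proportions = prop_df.loc[spots]

    return SpatialDataset(
        counts=mat,
        gene_ids=genes,
        spot_ids=spots,
        coords=coords,
        domains=domains,
        proportions=proportions,
        name=name or Path(matrix_path).resolve().parent.name,
    )


def read_dataset_dir(path: PathLike, name: Optional[str] = None) -> SpatialDataset:
    """Read a dataset directory using the standard file names."""
    path = Path(path)
    domains = path / "domains.csv"
    props = path / "proportions.csv"
    return read_spatial_dataset(
        path / "matrix.mtx",
        path / "features.tsv",
        path / "barcodes.tsv",
        path / "coords.csv",
        domains_path=domains if domains.exists() else None,
        proportions_path=props if props.exists() else None,
        name=name or path.name,
    )


def write_spatial_dataset(ds: SpatialDataset, outdir: PathLike) -> Path:
    """Write a dataset to a directory in the standard layout.

    The count matrix is written as canonically ordered Matrix Market
    triplets (column-major), so write -> read -> write is byte-stable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coo = sp.csc_matrix(ds.counts).tocoo()
    sio.mmwrite(str(outdir / "matrix.mtx"), coo, field="integer")
    pd.Series(ds.gene_ids).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(ds.spot_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    ).to_csv(outdir / "coords.csv", index=False)
    if ds.domains is not None:
        pd.DataFrame({"spot_id": ds.spot_ids, "domain": ds.domains}).to_csv(
            outdir / "domains.csv", index=False
        )
    if ds.proportions is not None:
        ds.proportions.rename_axis("spot_id").to_csv(outdir / "proportions.csv")
    log.info("wrote dataset %s (%d genes x %d spots) to %s",
             ds.name, ds.n_genes, ds.n_spots, outdir)
    return outdir


def read_single_cell_reference(
    matrix_path: PathLike,
    features_path: PathLike,
    barcodes_path: PathLike,
    labels_path: PathLike,
) -> SingleCellReference:
    """Read a labelled single-cell count matrix (same triplet layout).

    ``labels_path`` is a CSV with columns ``cell_id,cell_type``.
    """
    genes = _read_id_column(features_path)
    cells = _read_id_column(barcodes_path)
    mat = sio.mmread(str(matrix_path))
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if mat.shape == (len(cells), len(genes)) and len(genes) != len(cells):
        mat = mat.T
    if mat.shape != (len(genes), len(cells)):
        raise DimensionMismatchError(
            f"matrix shape {mat.shape} vs {len(genes)} genes x {len(cells)} cells"
        )
    lab = pd.read_csv(labels_path)
    lab["cell_id"] = lab["cell_id"].astype(str)
    lab = lab.set_index("cell_id")
    if set(lab.index) != set(cells):
        raise DimensionMismatchError(
            f"labels cover {len(lab)} cells, matrix has {len(cells)}"
        )
    return SingleCellReference(
        counts=mat,
        gene_ids=genes,
        cell_ids=cells,
        cell_types=lab.loc[cells, "cell_type"].to_numpy(),
    )
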