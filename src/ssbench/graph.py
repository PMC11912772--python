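"""Spot neighbor-graph construction from 2D coordinates.

The default is a union-symmetrized k-nearest-neighbor graph with k=6,
matching the hexagonal packing of Visium-style lattices; Delaunay
triangulation is available as an alternative.  Distance ties are broken by
the lower spot index so the graph is a deterministic function of the
coordinates.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .datamodel import NeighborGraph, ValidationError


def _knn_edges(coords: np.ndarray, k: int, chunk: int = 512) -> sp.csr_matrix:
    n = coords.shape[0]
    rows = np.empty(n * k, dtype=np.int64)
    cols = np.empty(n * k, dtype=np.int64)
    pos = 0
    order_key = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = coords[start:stop]
        d = np.sqrt(((block[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        for local_i in range(stop - start):
            i = start + local_i
            di = d[local_i].copy()
            di[i] = np.inf  # exclude self
            # stable sort on distance, ties to lower index
            nn = np.lexsort((order_key, di))[:k]
            rows[pos : pos + k] = i
            cols[pos : pos + k] = nn
            pos += k
    adj = sp.csr_matrix(
        (np.ones(n * k), (rows, cols)), shape=(n, n)
    )
    adj = ((adj + adj.T) > 0).astype(float)  # union symmetrization
    adj.setdiag(0)
    adj.eliminate_zeros()
    return adj


def _delaunay_edges(coords: np.ndarray) -> sp.csr_matrix:
    from scipy.spatial import Delaunay

    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] != coords.shape[0]:
        raise ValidationError("duplicate coordinates not allowed with delaunay")
    tri = Delaunay(coords)
    n = coords.shape[0]
    rows, cols = [], []
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(3):
                if a != b:
                    rows.append(simplex[a])
                    cols.append(simplex[b])
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj = (adj > 0).astype(float)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return adj


def build_neighbor_graph(
    coords: np.ndarray, method: str = "knn", k: int = 6
) -> NeighborGraph:
    """Build a symmetric spot adjacency from coordinates.

    Parameters
    ----------
    coords : array, shape (n_spots, 2)
    method : {"knn", "delaunay"}
        ``knn`` links each spot to its k nearest neighbors and symmetrizes
        by union; ``delaunay`` uses the Delaunay triangulation edges.
    k : int
        Neighbor count for ``knn`` (default 6, the hexagonal lattice
        coordination number).  Must be smaller than the spot count.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValidationError(f"coords must be (n, 2), got {coords.shape}")
    n = coords.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 spots to build a graph")
    if method == "knn":
        if k >= n:
            raise ValidationError(f"k={k} must be smaller than spot count {n}")
        adj = _knn_edges(coords, k)
        return NeighborGraph(adjacency=adj, k_param=k, method="knn")
    if method == "delaunay":
        adj = _delaunay_edges(coords)
        return NeighborGraph(adjacency=adj, k_param=None, method="delaunay")
    raise ValidationError(f"unknown neighbor method {method!r}")
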