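"""Spatial-level statistics on the spot lattice.

Seven statistics describe how expression and annotation organize in space:
the domain transition matrix (TM), the neighborhood enrichment z-score
matrix (NEM), per-domain graph centralities (CSM: group degree, clustering
coefficient, group closeness), univariate Moran's I, nearest-neighbor
expression correlation, cell-type interaction strength, and a
proportion-weighted Ripley L statistic.

Moran's I for values x over adjacency w is

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with W = sum_ij w_ij; a constant vector returns 0 with a warning (the
formula is 0/0 there).
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .datamodel import (
    MetricSample,
    NeighborGraph,
    SpatialDataset,
    ValidationError,
)
from .preprocess import dataset_log2cpm

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- Moran's I

def morans_i(values: np.ndarray, graph: NeighborGraph) -> float:
    """Global spatial autocorrelation of one per-spot variable."""
    x = np.asarray(values, dtype=float)
    if x.shape != (graph.n_spots,):
        raise ValidationError(
            f"{x.shape[0]} values vs {graph.n_spots} graph spots"
        )
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        warnings.warn("Moran's I of a constant vector; returning 0")
        return 0.0
    W = graph.total_weight
    num = float(xc @ (graph.adjacency @ xc))
    return (x.size / W) * num / denom


def morans_i_genes(expr: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Vectorized Moran's I for each row of a genes x spots matrix.

    Constant rows get 0 (same convention as :func:`morans_i`).
    """
    X = np.asarray(expr, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = (Xc**2).sum(axis=1)
    num = (Xc * (graph.adjacency @ Xc.T).T).sum(axis=1)
    W = graph.total_weight
    out = np.zeros(X.shape[0])
    ok = denom > 0
    out[ok] = (X.shape[1] / W) * num[ok] / denom[ok]
    return out


# ------------------------------------------------------------ domain labels

def _domain_onehot(ds: SpatialDataset) -> tuple[np.ndarray, list]:
    if ds.domains is None:
        raise ValidationError("dataset has no spatial-domain labels")
    labels = sorted(set(ds.domains.tolist()), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    onehot = np.zeros((ds.n_spots, len(labels)))
    for i, lab in enumerate(ds.domains.tolist()):
        onehot[i, index[lab]] = 1.0
    return onehot, labels


def _pair_counts(onehot: np.ndarray, adj: sp.csr_matrix) -> np.ndarray:
    """K x K matrix of ordered neighbor-pair counts by domain."""
    return onehot.T @ (adj @ onehot)


def transition_matrix(
    ds: SpatialDataset, graph: NeighborGraph
) -> tuple[np.ndarray, list]:
    """Row-stochastic domain transition frequencies over neighbor pairs.

    Entry (a, b) is the fraction of ordered neighbor pairs starting in
    domain a that end in domain b.  A domain with no neighbor pairs gets a
    uniform row (with a warning).
    """
    onehot, labels = _domain_onehot(ds)
    counts = _pair_counts(onehot, graph.adjacency)
    rowsum = counts.sum(axis=1, keepdims=True)
    K = len(labels)
    tm = np.full((K, K), 1.0 / K)
    empty = rowsum.ravel() == 0
    if empty.any():
        warnings.warn(
            f"domains with no neighbor pairs get uniform rows: "
            f"{[labels[i] for i in np.nonzero(empty)[0]]}"
        )
    nz = ~empty
    tm[nz] = counts[nz] / rowsum[nz]
    return tm, labels


def neighborhood_enrichment(
    ds: SpatialDataset,
    graph: NeighborGraph,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, list]:
    """Z-scores of inter-domain edge counts against a label-permutation null.

    NEM_ij = (x_ij - mu_ij) / sigma_ij where x_ij counts ordered neighbor
    pairs between domains i and j, and mu/sigma are the mean/sd of the same
    count under ``n_perm`` seeded permutations of the domain labels.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100 for a stable null")
    onehot, labels = _domain_onehot(ds)
    sizes = onehot.sum(axis=0)
    if (sizes == 1).any():
        warnings.warn("some domains contain a single spot")
    obs = _pair_counts(onehot, graph.adjacency)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm,) + obs.shape)
    for p in range(n_perm):
        idx = rng.permutation(ds.n_spots)
        perms[p] = _pair_counts(onehot[idx], graph.adjacency)
    mu = perms.mean(axis=0)
    sd = perms.std(axis=0)
    z = np.zeros_like(obs)
    ok = sd > 0
    if not ok.all():
        warnings.warn("zero permutation sd for some domain pairs; z set to 0")
    z[ok] = (obs[ok] - mu[ok]) / sd[ok]
    return z, labels


def centrality_scores(
    ds: SpatialDataset, graph: NeighborGraph
) -> tuple[np.ndarray, list]:
    """Per-domain [G1, G2, G3] graph summaries (K x 3).

    G1 group degree centrality: |N(C_k)| / (N - |C_k|) with N(C_k) the
    non-member spots adjacent to the domain.  G2: mean local clustering
    coefficient over members (degree < 2 contributes 0).  G3 group
    closeness: |V - C_k| / sum of shortest-path distances from non-members
    to the domain; unreachable spots are excluded with a logged count.
    """
    import networkx as nx

    onehot, labels = _domain_onehot(ds)
    K = len(labels)
    n = ds.n_spots
    if K == n:
        raise ValidationError("every spot is its own domain; centralities undefined")
    G = graph.to_networkx()
    clustering = nx.clustering(G)
    csm = np.zeros((K, 3))
    for k, lab in enumerate(labels):
        members = set(np.nonzero(onehot[:, k])[0].tolist())
        outside = n - len(members)
        # G1: boundary neighbors
        boundary = set()
        for v in members:
            boundary.update(G.neighbors(v))
        boundary -= members
        csm[k, 0] = len(boundary) / outside if outside else 0.0
        # G2: mean clustering coefficient over members
        csm[k, 1] = float(np.mean([clustering[v] for v in members]))
        # G3: group closeness via multi-source BFS
        dist = nx.multi_source_dijkstra_path_length(G, members, weight=None)
        dsum = 0.0
        reached = 0
        for v, dv in dist.items():
            if v not in members:
                dsum += dv
                reached += 1
        unreachable = outside - reached
        if unreachable:
            log.info(
                "G3(%s): %d spots unreachable from the domain, excluded",
                lab, unreachable,
            )
        csm[k, 2] = reached / dsum if dsum > 0 else 0.0
    return csm, labels


# --------------------------------------------------- expression-based stats

def nn_correlation(
    ds: SpatialDataset, graph: Optional[NeighborGraph] = None
) -> MetricSample:
    """Per-gene Pearson correlation of each spot with its nearest neighbor.

    The nearest neighbor is the spot at the smallest Euclidean distance
    (ties to the lower index).  Constant genes are skipped and tallied.
    """
    n = ds.n_spots
    nn = np.empty(n, dtype=np.int64)
    order_key = np.arange(n)
    for start in range(0, n, 512):
        stop = min(start + 512, n)
        d = np.sqrt(
            ((ds.coords[start:stop, None, :] - ds.coords[None, :, :]) ** 2).sum(-1)
        )
        for li in range(stop - start):
            i = start + li
            di = d[li].copy()
            di[i] = np.inf
            nn[i] = np.lexsort((order_key, di))[0]
    expr = dataset_log2cpm(ds)
    a = expr
    b = expr[:, nn]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    ok = denom > 0
    vals = (ac * bc).sum(axis=1)[ok] / denom[ok]
    n_dropped = int((~ok).sum())
    return MetricSample(
        name="nn_correlation",
        level="spatial",
        values=vals,
        source=ds.name,
        n_dropped=n_dropped,
    )


def celltype_interaction(
    ds: SpatialDataset, graph: NeighborGraph
) -> MetricSample:
    """Neighbor-weighted co-occurrence of cell types from spot proportions.

    For each unordered type pair (a, b) the statistic is the average of
    p_ia * p_jb over ordered neighbor spot pairs (i, j); a single cell type
    gives the vector [1].
    """
    if ds.proportions is None:
        raise ValidationError("dataset has no cell-type proportions")
    P = ds.proportions.to_numpy(dtype=float)
    n_pairs = graph.total_weight
    M = P.T @ (graph.adjacency @ P) / n_pairs
    T = P.shape[1]
    iu = np.triu_indices(T)
    return MetricSample(
        name="celltype_interaction",
        level="spatial",
        values=M[iu],
        source=ds.name,
    )


def l_statistic(
    ds: SpatialDataset, radii: Sequence[float]
) -> MetricSample:
    """Proportion-weighted Ripley cross-L over cell-type pairs.

    For types (a, b), K_ab(r) = |A| * sum_{i != j} p_ia p_jb 1[d_ij <= r]
    / (W_a * W_b) with W_t = sum_i p_it and |A| the bounding-box area;
    L = sqrt(K / pi).  Output is flattened type-pair-major over radii.
    """
    if ds.proportions is None:
        raise ValidationError("dataset has no cell-type proportions")
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or (radii <= 0).any() or (np.diff(radii) <= 0).any():
        raise ValidationError("radii must be positive and strictly ascending")
    coords = ds.coords
    span = coords.max(axis=0) - coords.min(axis=0)
    area = float(np.prod(np.where(span > 0, span, 1.0)))
    diam = float(np.sqrt((span**2).sum()))
    if (radii > diam).any():
        warnings.warn("some radii exceed the coordinate-domain diameter")
    P = ds.proportions.to_numpy(dtype=float)
    n = ds.n_spots
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)  # exclude i = j
    W = P.sum(axis=0)
    T = P.shape[1]
    iu, ju = np.triu_indices(T)
    out = np.empty(len(iu) * radii.size)
    pos = 0
    for a, b in zip(iu, ju):
        for r in radii:
            mask = d <= r
            s = float(P[:, a] @ (mask @ P[:, b]))
            K = area * s / (W[a] * W[b])
            out[pos] = np.sqrt(K / np.pi)
            pos += 1
    return MetricSample(
        name="l_statistic", level="spatial", values=out, source=ds.name
    )
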