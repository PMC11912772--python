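"""Downstream-task evaluations and simple built-in baseline analyses.

Four tasks compare the analysis of a simulated dataset against the same
analysis of the real dataset: spatial clustering (ARI/NMI), cell-type
deconvolution (RMSE / Jensen-Shannon divergence), spatially variable gene
(SVG) identification (precision/recall), and spatial cross-correlation
(bivariate Moran's I matrices compared by cosine similarity and the Mantel
statistic).

Any external method can plug in: an evaluation only consumes the task's
output type (a partition, a proportion matrix, a gene set, a
cross-correlation matrix), never the tool that produced it.  The built-in
baselines (PCA+k-means clustering, NNLS deconvolution, Moran-permutation
SVG detection) keep the framework self-contained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .datamodel import (
    NeighborGraph,
    SingleCellReference,
    SpatialDataset,
    ValidationError,
)
from .preprocess import dataset_log2cpm
from .spatial_metrics import morans_i_genes

log = logging.getLogger(__name__)


# -------------------------------------------------------------- clustering

def _check_partitions(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"partitions must be equal-length 1D: {a.shape} vs {b.shape}"
        )
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same spots.

    Two single-cluster partitions agree perfectly and return 1 (the
    pair-counting formula is 0/0 there).
    """
    a, b = _check_partitions(labels_a, labels_b)
    if len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1:
        return 1.0
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by the mean of the two entropies."""
    a, b = _check_partitions(labels_a, labels_b)
    if len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1:
        return 1.0
    return float(
        normalized_mutual_info_score(a, b, average_method="arithmetic")
    )


def baseline_spatial_clustering(
    ds: SpatialDataset,
    K: int,
    smooth_weight: float = 0.5,
    seed: int = 0,
    n_pcs: int = 10,
) -> np.ndarray:
    """Seeded k-means on expression PCs plus (optionally) scaled coordinates.

    The feature block is the top principal components of per-gene
    standardized log2-CPM (each gene centered and scaled to unit variance,
    so high-mean genes do not dominate), scaled to unit total variance;
    the coordinate block is min-max scaled and weighted by
    ``smooth_weight`` (0 reduces to expression-only clustering).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if K < 2:
        raise ValidationError("K must be >= 2")
    if K > ds.n_spots:
        raise ValidationError(f"K={K} exceeds spot count {ds.n_spots}")
    expr = dataset_log2cpm(ds).T  # spots x genes
    sd = expr.std(axis=0)
    expr = (expr - expr.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_comp = min(n_pcs, expr.shape[0] - 1, expr.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(expr)
    total = np.sqrt((pcs**2).sum(axis=1).mean())
    if total > 0:
        pcs = pcs / total
    span = ds.coords.max(axis=0) - ds.coords.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    xy = (ds.coords - ds.coords.min(axis=0)) / span
    feats = np.hstack([pcs, smooth_weight * xy])
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    return km.fit_predict(feats)


# ----------------------------------------------------------- deconvolution

@dataclass
class ProportionPair:
    """True (T) and predicted (P) spots x cell-types proportion matrices."""

    T: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.T = np.atleast_2d(np.asarray(self.T, dtype=float).T).T
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float).T).T
        if self.T.shape != self.P.shape:
            raise ValidationError(
                f"proportion shapes differ: {self.T.shape} vs {self.P.shape}"
            )
        for name, m in (("T", self.T), ("P", self.P)):
            if (m < -1e-12).any() or (m > 1 + 1e-12).any():
                raise ValidationError(f"{name} entries must lie in [0, 1]")

    @property
    def column_sums(self) -> np.ndarray:
        """S_k: per-type sums of the true proportions over spots."""
        return self.T.sum(axis=0)


def deconv_rmse(pp: ProportionPair) -> float:
    """Root mean square error, per-type normalized by S_k, averaged.

    RMSE = sqrt( (1/K) sum_k (1/S_k) sum_i (P_ik - T_ik)^2 ).
    """
    S = pp.column_sums
    if (S <= 0).any():
        bad = np.nonzero(S <= 0)[0].tolist()
        raise ValidationError(f"zero true-proportion sum for type(s) {bad}")
    K = pp.T.shape[1]
    per_type = ((pp.P - pp.T) ** 2).sum(axis=0) / S
    return float(np.sqrt(per_type.sum() / K))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


def deconv_jsd(pp: ProportionPair) -> float:
    """Jensen-Shannon divergence (natural log) averaged over cell types.

    Each type's proportion column is normalized over spots into a
    distribution; disjoint supports give the analytic maximum ln 2.
    """
    S_T = pp.T.sum(axis=0)
    S_P = pp.P.sum(axis=0)
    if (S_T <= 0).any() or (S_P <= 0).any():
        raise ValidationError("all-zero proportion column; JSD undefined")
    vals = []
    for k in range(pp.T.shape[1]):
        qt = pp.T[:, k] / S_T[k]
        qp = pp.P[:, k] / S_P[k]
        mid = 0.5 * (qt + qp)
        vals.append(0.5 * _kl(qt, mid) + 0.5 * _kl(qp, mid))
    return float(np.mean(vals))


def baseline_deconvolution(
    ds: SpatialDataset, ref: SingleCellReference
) -> np.ndarray:
    """Non-negative least squares of spot CPM profiles on type signatures.

    The signature matrix holds per-type mean CPM profiles of the reference
    cells over the shared gene set (at least 50 genes required); rows of
    the result are renormalized to sum to 1.
    """
    from scipy.optimize import nnls

    shared = [g for g in ds.gene_ids if g in set(ref.gene_ids)]
    if len(shared) < 50:
        raise ValidationError(
            f"only {len(shared)} shared genes; need >= 50 for deconvolution"
        )
    ds_idx = {g: i for i, g in enumerate(ds.gene_ids)}
    rf_idx = {g: i for i, g in enumerate(ref.gene_ids)}
    X = ds.counts[[ds_idx[g] for g in shared], :].astype(float)
    X = 1e6 * X / X.sum(axis=0)
    R = ref.counts[[rf_idx[g] for g in shared], :].astype(float)
    R = 1e6 * R / np.maximum(R.sum(axis=0), 1.0)
    types = sorted(set(ref.cell_types.tolist()), key=str)
    B = np.column_stack(
        [R[:, ref.cell_types == t].mean(axis=1) for t in types]
    )
    if np.linalg.matrix_rank(B) < B.shape[1]:
        warnings.warn("rank-deficient signature matrix; estimates unstable")
    out = np.empty((ds.n_spots, len(types)))
    for i in range(ds.n_spots):
        coef, _ = nnls(B, X[:, i])
        s = coef.sum()
        out[i] = coef / s if s > 0 else np.full(len(types), 1.0 / len(types))
    return out


# --------------------------------------------------------------------- SVG

def svg_precision_recall(real_svg, sim_svg) -> tuple[float, float]:
    """Precision and recall of a simulated SVG set against the real one.

    Real-data detections are treated as truth: precision = TP/(TP+FP) over
    the simulated set, recall = TP/(TP+FN) over the real set.
    """
    real_svg = set(real_svg)
    sim_svg = set(sim_svg)
    if not real_svg and not sim_svg:
        return 1.0, 1.0
    tp = len(real_svg & sim_svg)
    if not sim_svg:
        warnings.warn("empty simulated SVG set; precision set to 0")
        precision = 0.0
    else:
        precision = tp / len(sim_svg)
    recall = tp / len(real_svg) if real_svg else 1.0
    return float(precision), float(recall)


def baseline_svg_detector(
    ds: SpatialDataset,
    graph: NeighborGraph,
    n_perm: int = 200,
    fdr: float = 0.05,
    seed: int = 0,
) -> set:
    """Moran's-I permutation test per gene with Benjamini-Hochberg control.

    Expression is square-root-CPM transformed (variance stabilizing for
    counts, which keeps sparse genes' zero/non-zero jumps from swamping
    the autocorrelation signal).  Spot values are permuted jointly across
    genes per permutation; one-sided p-values (positive autocorrelation)
    are BH-adjusted and genes below the ``fdr`` threshold returned.
    """
    from statsmodels.stats.multitest import multipletests

    if n_perm < 50:
        raise ValidationError("n_perm must be >= 50")
    libs = ds.counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValidationError("zero library size spot; SVG detection undefined")
    expr = np.sqrt(1e6 * ds.counts / libs)
    obs = morans_i_genes(expr, graph)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(ds.n_genes)
    for _ in range(n_perm):
        idx = rng.permutation(ds.n_spots)
        exceed += morans_i_genes(expr[:, idx], graph) >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return {g for g, r in zip(ds.gene_ids, reject) if r}


# ------------------------------------------------- spatial cross-correlation

def top_morans_genes(
    ds: SpatialDataset, graph: NeighborGraph, n: int = 50
) -> list:
    """The n most spatially autocorrelated genes (ties by gene id)."""
    scores = morans_i_genes(dataset_log2cpm(ds), graph)
    order = sorted(
        range(ds.n_genes), key=lambda i: (-scores[i], ds.gene_ids[i])
    )
    return [ds.gene_ids[i] for i in order[: min(n, ds.n_genes)]]


def bivariate_morans_matrix(
    ds: SpatialDataset,
    graph: NeighborGraph,
    genes: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Gene x gene bivariate Moran's I on log2-CPM.

    I_XY = (N/W) sum_ij w_ij (x_i - xbar)(y_j - ybar)
           / ( sqrt(sum (x - xbar)^2) sqrt(sum (y - ybar)^2) );

    the diagonal therefore equals each gene's univariate Moran's I.
    Constant genes get zero rows/columns with a warning.
    """
    if genes is None:
        genes = ds.gene_ids
    if len(genes) < 2:
        raise ValidationError("need >= 2 genes for a cross-correlation matrix")
    sub = ds.subset_genes(list(genes))
    X = dataset_log2cpm(sub)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    const = norms == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant genes; their cross-correlation "
            "rows/columns set to 0"
        )
    safe = np.where(const, 1.0, norms)
    W = graph.total_weight
    M = (sub.n_spots / W) * (Xc @ (graph.adjacency @ Xc.T)) / np.outer(safe, safe)
    M[const, :] = 0.0
    M[:, const] = 0.0
    return M


def cross_corr_agreement(
    real_m: np.ndarray, sim_m: np.ndarray
) -> tuple[float, float]:
    """Cosine similarity and Mantel correlation of two matrices.

    Both operate on the flattened entries: cosine on the raw dot product,
    Mantel as the centered cross-product correlation.
    """
    A = np.asarray(real_m, dtype=float)
    B = np.asarray(sim_m, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(f"matrix shapes differ: {A.shape} vs {B.shape}")
    a = A.ravel()
    b = B.ravel()
    cosine = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    ac = a - a.mean()
    bc = b - b.mean()
    mantel = float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))
    return cosine, mantel
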