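"""Spot-level and gene-level data-property samples.

Each operation turns a dataset into a :class:`~ssbench.datamodel.MetricSample`
— the distribution of a property over spots or genes — which the KDE
two-sample comparison then scores against the same property on a reference
dataset.

TMM follows the trimmed-mean-of-M-values construction: per-gene log2
abundance ratios against a reference spot, doubly trimmed on the log-ratio
M and the absolute intensity A (per-tail rank trimming, 30% / 5%), then a
weighted mean exponentiated back.  The weight per gene is

    w_gk = (N_k - Y_gk) / (N_k Y_gk) + (N_r - Y_gr) / (N_r Y_gr)

and genes with a zero count in either library are excluded.  The reference
spot is the one whose upper-quartile abundance is closest to the mean
upper-quartile across spots.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np

from .datamodel import (
    MetricSample,
    MomentSummary,
    SpatialDataset,
    ValidationError,
)
from .preprocess import dataset_log2cpm

log = logging.getLogger(__name__)


def library_size(ds: SpatialDataset) -> MetricSample:
    """Per-spot total UMI count."""
    return MetricSample(
        name="library_size",
        level="spot",
        values=ds.library_sizes().astype(float),
        source=ds.name,
    )


def _choose_reference_spot(counts: np.ndarray) -> int:
    """Spot whose upper-quartile relative abundance is closest to the mean."""
    libs = counts.sum(axis=0)
    f75 = np.quantile(counts / libs, 0.75, axis=0)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factor(
    ds: SpatialDataset,
    ref_spot: Optional[int] = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    as_printed: bool = False,
) -> MetricSample:
    """Per-spot TMM normalization factor against a reference spot.

    ``as_printed=True`` switches the M-value to the ratio-of-logs variant
    for auditability; the default is the canonical difference of logs.
    """
    counts = ds.counts.astype(float)
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValidationError("zero-library-size spot; TMM undefined")
    r = _choose_reference_spot(counts) if ref_spot is None else int(ref_spot)
    yr = counts[:, r]
    Nr = libs[r]
    factors = np.empty(ds.n_spots)
    for k in range(ds.n_spots):
        yk = counts[:, k]
        Nk = libs[k]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            raise ValidationError(
                f"no co-expressed genes between spot {ds.spot_ids[k]!r} "
                f"and the reference"
            )
        lk = np.log2(yk[ok] / Nk)
        lr = np.log2(yr[ok] / Nr)
        if as_printed:
            with np.errstate(divide="ignore", invalid="ignore"):
                M = np.where(lr != 0, lk / lr, 0.0)
        else:
            M = lk - lr
        A = 0.5 * (lk + lr)
        w = (Nk - yk[ok]) / (Nk * yk[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        n = M.size
        loM = int(np.floor(n * trim_M))
        loA = int(np.floor(n * trim_A))
        rankM = np.argsort(np.argsort(M, kind="stable"), kind="stable")
        rankA = np.argsort(np.argsort(A, kind="stable"), kind="stable")
        keep = (
            (rankM >= loM)
            & (rankM < n - loM)
            & (rankA >= loA)
            & (rankA < n - loA)
        )
        if not keep.any():
            raise ValidationError(
                f"no genes survive TMM trimming for spot {ds.spot_ids[k]!r}"
            )
        wk = w[keep]
        mk = M[keep]
        if wk.sum() > 0:
            factors[k] = 2.0 ** (float(wk @ mk) / float(wk.sum()))
        else:
            factors[k] = 2.0 ** float(mk.mean())
    return MetricSample(
        name="tmm", level="spot", values=factors, source=ds.name
    )


def effective_library_size(ds: SpatialDataset, **tmm_kwargs) -> MetricSample:
    """Library size multiplied by the TMM factor, per spot."""
    tmm = tmm_factor(ds, **tmm_kwargs)
    return MetricSample(
        name="effective_library_size",
        level="spot",
        values=ds.library_sizes() * tmm.values,
        source=ds.name,
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0:
        warnings.warn("constant vector in z-scoring; scaled values set to 0")
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def scaled_moments(ds: SpatialDataset, axis: str) -> MomentSummary:
    """Per-spot or per-gene means/variances of log2-CPM, z-scored.

    axis="spot" summarizes each column of the log2-CPM matrix across genes;
    axis="gene" summarizes each row across spots.  The z-scoring is across
    the axis population (sample sd, ddof=1).
    """
    expr = dataset_log2cpm(ds)
    if axis == "spot":
        means = expr.mean(axis=0)
        variances = expr.var(axis=0, ddof=1)
    elif axis == "gene":
        means = expr.mean(axis=1)
        variances = expr.var(axis=1, ddof=1)
    else:
        raise ValidationError(f"axis must be 'spot' or 'gene', got {axis!r}")
    return MomentSummary(
        axis=axis,
        means=means,
        variances=variances,
        scaled_means=_zscore(means),
        scaled_variances=_zscore(variances),
    )


def fraction_zero(ds: SpatialDataset, axis: str) -> MetricSample:
    """Zero fraction of raw counts per spot or per gene."""
    if axis == "spot":
        vals = (ds.counts == 0).mean(axis=0)
    elif axis == "gene":
        vals = (ds.counts == 0).mean(axis=1)
    else:
        raise ValidationError(f"axis must be 'spot' or 'gene', got {axis!r}")
    return MetricSample(
        name=f"fraction_zero_{axis}", level=axis, values=vals, source=ds.name
    )


def relationship_sample(ds: SpatialDataset, kind: str) -> MetricSample:
    """Paired per-unit statistics for the bivariate density comparisons.

    kinds: ``libsize_vs_fraczero`` (per spot), ``mean_vs_variance`` and
    ``mean_vs_fraczero`` (per gene).  The higher-order relationships are
    taken on raw counts, where the count mean-variance law lives.
    """
    if kind == "libsize_vs_fraczero":
        a = library_size(ds).values
        b = fraction_zero(ds, "spot").values
        level = "spot"
    elif kind == "mean_vs_variance":
        a = ds.counts.mean(axis=1)
        b = ds.counts.var(axis=1, ddof=1)
        level = "gene"
    elif kind == "mean_vs_fraczero":
        a = ds.counts.mean(axis=1)
        b = fraction_zero(ds, "gene").values
        level = "gene"
    else:
        raise ValidationError(f"unknown relationship kind {kind!r}")
    return MetricSample(
        name=kind,
        level=level,
        values=np.column_stack([a, b]),
        source=ds.name,
    )


def pairwise_correlation_sample(
    ds: SpatialDataset,
    axis: str,
    max_pairs: int = 5000,
    seed: int = 0,
) -> MetricSample:
    """Pearson correlations of log2-CPM between sampled unit pairs.

    All C(n, 2) pairs are used when there are at most ``max_pairs``;
    otherwise a uniform without-replacement subsample of pairs.  Constant
    units are skipped (tallied in ``n_dropped``).
    """
    expr = dataset_log2cpm(ds)
    X = expr.T if axis == "spot" else expr  # units x features
    if axis not in ("spot", "gene"):
        raise ValidationError(f"axis must be 'spot' or 'gene', got {axis!r}")
    sd = X.std(axis=1)
    ok = sd > 0
    n_dropped = int((~ok).sum())
    X = X[ok]
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 non-constant units for correlations")
    total = n * (n - 1) // 2
    if total <= max_pairs:
        iu, ju = np.triu_indices(n, k=1)
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=max_pairs, replace=False)
        # map flat upper-triangle index to (i, j), row-major
        iu = (
            n - 2
            - np.floor(
                np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5
            )
        ).astype(np.int64)
        ju = (
            flat + iu + 1 - (iu * (2 * n - iu - 1)) // 2
        ).astype(np.int64)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    vals = (Xc[iu] * Xc[ju]).sum(axis=1) / (norms[iu] * norms[ju])
    return MetricSample(
        name=f"{axis}_correlation",
        level=axis,
        values=vals,
        source=ds.name,
        n_dropped=n_dropped,
    )
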