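"""Rank aggregation, consistency summaries and effect regressions.

Methods are ranked per metric by the raw KDE z statistic (ascending; lower
means closer to the real data; ties get the average rank) and a level's
overall score is the unweighted mean rank across that level's metrics.
Ranking on raw z rather than the [0, 1] transform is stated for
determinism — the transform is monotone, so the ordering is identical.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import SpatialDataset, ValidationError

log = logging.getLogger(__name__)


def overall_rank_score(scores: pd.DataFrame, level: str) -> pd.DataFrame:
    """Per-metric method ranks at one level plus the mean-rank overall score.

    ``scores`` is a score_table DataFrame.  Methods missing a metric are
    excluded from that metric's ranking with a warning.  Returns a
    DataFrame indexed by method with one column per metric and an
    ``overall_score`` column.
    """
    sub = scores[(scores["level"] == level) & scores["raw_z"].notna()]
    if sub.empty:
        raise ValidationError(f"no scored metrics at level {level!r}")
    pivot = sub.pivot_table(
        index="method", columns="metric", values="raw_z", aggfunc="mean"
    )
    if pivot.isna().any().any():
        missing = pivot.columns[pivot.isna().any()].tolist()
        warnings.warn(
            f"methods missing scores excluded from ranking for: {missing}"
        )
    ranks = pivot.rank(axis=0, method="average", ascending=True)
    out = ranks.copy()
    out["overall_score"] = ranks.mean(axis=1)
    return out


def dataset_consistency(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean raw KDE z per (method, dataset, level) over the level's metrics."""
    sub = scores[scores["raw_z"].notna()]
    if sub.empty:
        raise ValidationError("no scored KDE metrics in the table")
    out = (
        sub.groupby(["method", "dataset", "level"])["raw_z"]
        .mean()
        .rename("mean_kde_z")
        .reset_index()
    )
    return out


def concordance_index(true_scores, predicted_scores) -> float:
    """Fraction of true-ordered pairs whose predicted ordering agrees.

    Pairs with tied true values are excluded from the denominator;
    predicted ties receive half credit.
    """
    t = np.asarray(true_scores, dtype=float)
    p = np.asarray(predicted_scores, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size < 2:
        raise ValidationError("inputs must be equal-length 1D with >= 2 items")
    dt = t[:, None] - t[None, :]
    dp = p[:, None] - p[None, :]
    iu = np.triu_indices(t.size, k=1)
    dt, dp = dt[iu], dp[iu]
    comparable = dt != 0
    if not comparable.any():
        raise ValidationError("all true values tied; C-index undefined")
    agree = np.sign(dt[comparable]) == np.sign(dp[comparable])
    ties = dp[comparable] == 0
    credit = np.where(ties, 0.5, agree.astype(float))
    return float(credit.mean())


def model_effect_regression(
    scores: pd.DataFrame, metric: str
) -> pd.DataFrame:
    """OLS of the KDE statistic on method indicators, for one metric.

    The reference method is the first alphabetically; returns coefficient,
    standard error and two-sided p-value per term.
    """
    import statsmodels.formula.api as smf

    sub = scores[(scores["metric"] == metric) & scores["raw_z"].notna()].copy()
    methods = sorted(sub["method"].unique().tolist())
    if len(methods) < 2:
        raise ValidationError(
            f"need >= 2 methods with scores for metric {metric!r}"
        )
    sub["method"] = pd.Categorical(sub["method"], categories=methods)
    try:
        fit = smf.ols("raw_z ~ C(method)", data=sub).fit()
    except Exception as exc:  # pragma: no cover - statsmodels wraps errors
        raise ValidationError(f"regression failed: {exc}") from exc
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    return pd.DataFrame(
        {
            "coef": fit.params,
            "stderr": fit.bse,
            "pvalue": fit.pvalues,
        }
    )


def evaluation_grid(
    methods: Sequence[str],
    datasets: Sequence[str],
    metrics: Sequence[str],
) -> pd.DataFrame:
    """Result-ledger skeleton: one pending row per (method, dataset, metric)."""
    for name, items in (
        ("methods", methods),
        ("datasets", datasets),
        ("metrics", metrics),
    ):
        items = list(items)
        if not items:
            raise ValidationError(f"empty {name} list")
        if len(set(items)) != len(items):
            raise ValidationError(f"duplicate identifiers in {name}")
    rows = [
        {"method": m, "dataset": d, "metric": x, "status": "pending"}
        for m, d, x in itertools.product(methods, datasets, metrics)
    ]
    return pd.DataFrame(rows)


DEFAULT_SPOT_COUNTS = (200, 500, 1000, 3000, 5000)
DEFAULT_GENE_COUNTS = (200, 500, 1000)


def downsampling_grid(
    ds: SpatialDataset,
    spot_counts: Sequence[int] = DEFAULT_SPOT_COUNTS,
    gene_counts: Sequence[int] = DEFAULT_GENE_COUNTS,
    seed: int = 0,
) -> dict:
    """Seeded uniform subsamples at every (spots, genes) combination.

    One permutation per axis is drawn once and prefixes of it are used for
    every size, so smaller subsamples are nested inside larger ones.
    Coordinates are preserved.  Returns ``{(n_spots, n_genes): dataset}``.
    """
    spot_counts = list(spot_counts)
    gene_counts = list(gene_counts)
    for s in spot_counts:
        if s > ds.n_spots:
            raise ValidationError(
                f"requested {s} spots but dataset has {ds.n_spots}"
            )
    for g in gene_counts:
        if g > ds.n_genes:
            raise ValidationError(
                f"requested {g} genes but dataset has {ds.n_genes}"
            )
    rng = np.random.default_rng(seed)
    spot_order = rng.permutation(ds.n_spots)
    gene_order = rng.permutation(ds.n_genes)
    out = {}
    for s, g in itertools.product(spot_counts, gene_counts):
        sub = ds.subset_spots(np.sort(spot_order[:s]))
        keep = np.sort(gene_order[:g])
        sub = sub.subset_genes([ds.gene_ids[i] for i in keep])
        sub.name = f"{ds.name}_s{s}_g{g}"
        out[(s, g)] = sub
    return out
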