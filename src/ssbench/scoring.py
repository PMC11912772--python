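"""The 35-metric registry and the real-vs-simulated score table.

The registry enumerates every benchmark metric exactly once:

* 8 spot-level and 6 gene-level data properties, compared between real and
  simulated data by the KDE two-sample statistic;
* 7 spatial-level statistics, compared the same way on their flattened
  value vectors;
* 8 downstream-task agreement metrics (clustering ARI/NMI, deconvolution
  RMSE/JSD, SVG precision/recall, cross-correlation cosine/Mantel), which
  are direct agreement scores rather than density comparisons;
* 6 scalability identifiers ({runtime, memory} x {spot scaling, gene
  scaling, overall}); profiling is out of scope here, so these rows are
  carried with status ``not_scored``.

:func:`score_table` walks the registry for one real dataset and a named
collection of simulations and assembles one row per (method, metric);
failures are recorded with a reason, never silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import property_metrics as pm
from . import spatial_metrics as sm
from .datamodel import NeighborGraph, SpatialDataset, ValidationError
from .graph import build_neighbor_graph
from .kde import kde_test, minmax_transform
from .preprocess import dataset_log2cpm

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricDef:
    name: str
    level: str  # spot | gene | spatial | downstream | scalability
    kind: str  # kde | downstream | scalability
    extractor: Optional[Callable] = field(default=None, compare=False)


def _default_radii(ds: SpatialDataset) -> np.ndarray:
    span = ds.coords.max(axis=0) - ds.coords.min(axis=0)
    diam = float(np.sqrt((span**2).sum()))
    return diam * np.array([0.05, 0.10, 0.15, 0.20, 0.25])


def _x_library_size(ds, ctx):
    return pm.library_size(ds).values


def _x_tmm(ds, ctx):
    return pm.tmm_factor(ds).values


def _x_eff_lib(ds, ctx):
    return pm.effective_library_size(ds).values


def _x_scaled_mean_spot(ds, ctx):
    return pm.scaled_moments(ds, "spot").scaled_means


def _x_scaled_var_spot(ds, ctx):
    return pm.scaled_moments(ds, "spot").scaled_variances


def _x_frac_zero_spot(ds, ctx):
    return pm.fraction_zero(ds, "spot").values


def _x_lib_vs_zero(ds, ctx):
    return pm.relationship_sample(ds, "libsize_vs_fraczero").values


def _x_spot_corr(ds, ctx):
    return pm.pairwise_correlation_sample(
        ds, "spot", max_pairs=ctx.get("max_pairs", 5000), seed=ctx["seed"]
    ).values


def _x_frac_zero_gene(ds, ctx):
    return pm.fraction_zero(ds, "gene").values


def _x_scaled_mean_gene(ds, ctx):
    return pm.scaled_moments(ds, "gene").scaled_means


def _x_scaled_var_gene(ds, ctx):
    return pm.scaled_moments(ds, "gene").scaled_variances


def _x_mean_vs_var(ds, ctx):
    return pm.relationship_sample(ds, "mean_vs_variance").values


def _x_mean_vs_zero(ds, ctx):
    return pm.relationship_sample(ds, "mean_vs_fraczero").values


def _x_gene_corr(ds, ctx):
    return pm.pairwise_correlation_sample(
        ds, "gene", max_pairs=ctx.get("max_pairs", 5000), seed=ctx["seed"]
    ).values


def _x_tm(ds, ctx):
    tm, _ = sm.transition_matrix(ds, ctx["graph"])
    return tm.ravel()


def _x_nem(ds, ctx):
    nem, _ = sm.neighborhood_enrichment(
        ds, ctx["graph"], n_perm=ctx.get("nem_perm", 1000), seed=ctx["seed"]
    )
    return nem.ravel()


def _x_csm(ds, ctx):
    csm, _ = sm.centrality_scores(ds, ctx["graph"])
    return csm.ravel()


def _x_ct_interaction(ds, ctx):
    return sm.celltype_interaction(ds, ctx["graph"]).values


def _x_morans(ds, ctx):
    return sm.morans_i_genes(dataset_log2cpm(ds), ctx["graph"])


def _x_lstat(ds, ctx):
    radii = ctx.get("radii")
    if radii is None:
        radii = _default_radii(ds)
    return sm.l_statistic(ds, radii).values


def _x_nn_corr(ds, ctx):
    return sm.nn_correlation(ds).values


def default_registry() -> list[MetricDef]:
    """The 35 benchmark metric identifiers, enumerated exactly once."""
    defs = [
        # -- spot-level data properties (8)
        MetricDef("library_size", "spot", "kde", _x_library_size),
        MetricDef("tmm", "spot", "kde", _x_tmm),
        MetricDef("effective_library_size", "spot", "kde", _x_eff_lib),
        MetricDef("scaled_mean_spot", "spot", "kde", _x_scaled_mean_spot),
        MetricDef("scaled_variance_spot", "spot", "kde", _x_scaled_var_spot),
        MetricDef("fraction_zero_spot", "spot", "kde", _x_frac_zero_spot),
        MetricDef("libsize_vs_fraczero", "spot", "kde", _x_lib_vs_zero),
        MetricDef("spot_correlation", "spot", "kde", _x_spot_corr),
        # -- gene-level data properties (6)
        MetricDef("fraction_zero_gene", "gene", "kde", _x_frac_zero_gene),
        MetricDef("scaled_mean_gene", "gene", "kde", _x_scaled_mean_gene),
        MetricDef("scaled_variance_gene", "gene", "kde", _x_scaled_var_gene),
        MetricDef("mean_vs_variance", "gene", "kde", _x_mean_vs_var),
        MetricDef("mean_vs_fraczero", "gene", "kde", _x_mean_vs_zero),
        MetricDef("gene_correlation", "gene", "kde", _x_gene_corr),
        # -- spatial-level data properties (7)
        MetricDef("transition_matrix", "spatial", "kde", _x_tm),
        MetricDef("neighborhood_enrichment", "spatial", "kde", _x_nem),
        MetricDef("centrality_scores", "spatial", "kde", _x_csm),
        MetricDef("celltype_interaction", "spatial", "kde", _x_ct_interaction),
        MetricDef("morans_i", "spatial", "kde", _x_morans),
        MetricDef("l_statistic", "spatial", "kde", _x_lstat),
        MetricDef("nn_correlation", "spatial", "kde", _x_nn_corr),
        # -- downstream agreement metrics (8)
        MetricDef("clustering_ari", "downstream", "downstream"),
        MetricDef("clustering_nmi", "downstream", "downstream"),
        MetricDef("deconv_rmse", "downstream", "downstream"),
        MetricDef("deconv_jsd", "downstream", "downstream"),
        MetricDef("svg_precision", "downstream", "downstream"),
        MetricDef("svg_recall", "downstream", "downstream"),
        MetricDef("crosscorr_cosine", "downstream", "downstream"),
        MetricDef("crosscorr_mantel", "downstream", "downstream"),
        # -- scalability identifiers (6); profiling not scored here
        MetricDef("runtime_spot_scaling", "scalability", "scalability"),
        MetricDef("runtime_gene_scaling", "scalability", "scalability"),
        MetricDef("runtime_overall", "scalability", "scalability"),
        MetricDef("memory_spot_scaling", "scalability", "scalability"),
        MetricDef("memory_gene_scaling", "scalability", "scalability"),
        MetricDef("memory_overall", "scalability", "scalability"),
    ]
    assert len(defs) == 35
    return defs


def registry_names(registry: Optional[list] = None) -> list:
    return [m.name for m in (registry or default_registry())]


def _downstream_values(real, sims, graph, seed, ctx) -> dict:
    """Compute the 8 downstream agreement metrics per method (best effort)."""
    from . import downstream as dse

    out = {m: {} for m in sims}
    reasons = {m: {} for m in sims}
    K = len(set(real.domains.tolist())) if real.domains is not None else None
    real_labels = None
    if K is not None and K >= 2:
        real_labels = dse.baseline_spatial_clustering(real, K, seed=seed)
    svg_real = dse.baseline_svg_detector(
        real, graph, n_perm=ctx.get("svg_perm", 200), seed=seed
    )
    genes = dse.top_morans_genes(real, graph, n=ctx.get("crosscorr_genes", 50))
    real_ccm = dse.bivariate_morans_matrix(real, graph, genes=genes)
    for method, sim in sims.items():
        # clustering
        if real_labels is None:
            reasons[method]["clustering_ari"] = "real dataset has no domains"
            reasons[method]["clustering_nmi"] = "real dataset has no domains"
        else:
            sim_labels = dse.baseline_spatial_clustering(sim, K, seed=seed)
            out[method]["clustering_ari"] = dse.ari(real_labels, sim_labels)
            out[method]["clustering_nmi"] = dse.nmi(real_labels, sim_labels)
        # deconvolution agreement on attached proportions
        if real.proportions is None or sim.proportions is None:
            reasons[method]["deconv_rmse"] = "missing cell-type proportions"
            reasons[method]["deconv_jsd"] = "missing cell-type proportions"
        else:
            pp = dse.ProportionPair(
                T=real.proportions.to_numpy(float),
                P=sim.proportions.to_numpy(float),
            )
            out[method]["deconv_rmse"] = dse.deconv_rmse(pp)
            out[method]["deconv_jsd"] = dse.deconv_jsd(pp)
        # SVG identification
        svg_sim = dse.baseline_svg_detector(
            sim, graph, n_perm=ctx.get("svg_perm", 200), seed=seed
        )
        prec, rec = dse.svg_precision_recall(svg_real, svg_sim)
        out[method]["svg_precision"] = prec
        out[method]["svg_recall"] = rec
        # spatial cross-correlation
        sim_ccm = dse.bivariate_morans_matrix(sim, graph, genes=genes)
        cos, mantel = dse.cross_corr_agreement(real_ccm, sim_ccm)
        out[method]["crosscorr_cosine"] = cos
        out[method]["crosscorr_mantel"] = mantel
    return out, reasons


def score_table(
    real: SpatialDataset,
    sims: dict,
    registry: Optional[list] = None,
    graph: Optional[NeighborGraph] = None,
    n_perm: int = 200,
    seed: int = 0,
    max_points: int = 2000,
    include_downstream: bool = True,
    **ctx_extra,
) -> pd.DataFrame:
    """Score every simulation against the real dataset on every metric.

    Returns a DataFrame with one row per (method, metric): columns
    ``method, dataset, metric, level, statistic, raw_z, value, transformed,
    status``.  KDE metrics carry T in ``statistic`` and the standardized z
    in ``raw_z``; downstream metrics carry their agreement score in
    ``value``.
    """
    if not sims:
        raise ValidationError("empty simulation collection")
    registry = registry or default_registry()
    if graph is None:
        graph = build_neighbor_graph(real.coords)
    shared = set(real.gene_ids)
    for name, sim in sims.items():
        if set(sim.gene_ids) != shared:
            raise ValidationError(
                f"simulation {name!r} does not share the real gene namespace"
            )
    ctx = {"graph": graph, "seed": seed, **ctx_extra}

    # real-side KDE samples, computed once
    real_samples = {}
    real_fail = {}
    for mdef in registry:
        if mdef.kind != "kde":
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                real_samples[mdef.name] = mdef.extractor(real, ctx)
        except (ValidationError, ValueError) as exc:
            real_fail[mdef.name] = str(exc)

    downstream_vals, downstream_reasons = ({}, {})
    if include_downstream:
        downstream_vals, downstream_reasons = _downstream_values(
            real, sims, graph, seed, ctx
        )

    rows = []
    for method, sim in sims.items():
        for mdef in registry:
            row = {
                "method": method,
                "dataset": real.name,
                "metric": mdef.name,
                "level": mdef.level,
                "statistic": np.nan,
                "raw_z": np.nan,
                "value": np.nan,
                "transformed": np.nan,
                "status": "ok",
            }
            if mdef.kind == "scalability":
                row["status"] = "not_scored:scalability profiling out of scope"
            elif mdef.kind == "downstream":
                if not include_downstream:
                    row["status"] = "not_scored:downstream disabled"
                elif mdef.name in downstream_vals.get(method, {}):
                    row["value"] = downstream_vals[method][mdef.name]
                else:
                    reason = downstream_reasons.get(method, {}).get(
                        mdef.name, "unavailable"
                    )
                    row["status"] = f"failed:{reason}"
            else:
                if mdef.name in real_fail:
                    row["status"] = f"failed:real:{real_fail[mdef.name]}"
                else:
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            sim_sample = mdef.extractor(sim, ctx)
                            res = kde_test(
                                real_samples[mdef.name],
                                sim_sample,
                                n_perm=n_perm,
                                seed=seed,
                                max_points=max_points,
                            )
                        row["statistic"] = res.T
                        row["raw_z"] = res.z
                    except (ValidationError, ValueError) as exc:
                        row["status"] = f"failed:{exc}"
            rows.append(row)
    table = pd.DataFrame(rows)

    # min-max transform per metric across methods (KDE rows only)
    for metric, grp in table.groupby("metric"):
        mask = (table["metric"] == metric) & table["raw_z"].notna()
        if mask.sum() >= 1:
            table.loc[mask, "transformed"] = minmax_transform(
                table.loc[mask, "raw_z"].to_numpy()
            )
    return table
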