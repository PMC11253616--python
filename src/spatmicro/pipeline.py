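"""Three-tier pipeline runner with a reproducible run manifest.

``run_pipeline`` executes diversity -> colocalization -> mark equality
-> neighborhood -> keystone on a cell table (real or simulated), writes
every result as tidy CSV, and records a manifest (config echo, package
versions, seed, SHA-256 digest of every output). One global seed fans
out to all stochastic stages, so a run is reproducible from a single
integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc, diversity, keystone, mark_equality, neighborhood
from .data_model import tabulate_abundance
from .synthetic import SimulationConfig, config_to_dict, simulate_study

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("spatmicro")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and stratum."""


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, with study defaults."""

    radius_um: float = 5.0
    rmax_um: float = 10.0
    control_treatment: str = "water"
    baseline_day: int = -8
    recovery_day: int = 35
    min_total_count: int = 2000
    min_prevalence: float = 0.25
    log2fc_threshold: float = 1.0
    signif_alpha: float = 0.05
    effsize_alpha: float = 0.1
    effsize_large: float = 0.14
    richness_percentile: float = 75.0
    abundance_percentile: float = 80.0
    correlation_percentile: float = 75.0
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        positive = ["radius_um", "rmax_um", "min_total_count", "min_prevalence",
                    "log2fc_threshold", "signif_alpha", "effsize_alpha", "effsize_large"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")
        if self.radius_um > self.rmax_um:
            raise PipelineError("config: radius_um must not exceed rmax_um")


def _write(df: pd.DataFrame, outdir: str, name: str, outputs: dict,
           index: bool = False) -> None:
    path = os.path.join(outdir, name)
    df.to_csv(path, index=index)
    with open(path, "rb") as fh:
        outputs[name] = hashlib.sha256(fh.read()).hexdigest()


def run_pipeline(
    config: RunConfig,
    outdir: str,
    cells: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    sim_config: SimulationConfig | None = None,
) -> dict:
    """Run all tiers; returns the manifest dict (also written to disk).

    Either pass ``cells`` and ``meta`` or a ``sim_config`` to simulate
    them first.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    outputs: dict[str, str] = {}
    t0 = time.time()

    if cells is None or meta is None:
        if sim_config is None:
            raise PipelineError("stage input: provide cells+meta or sim_config")
        log.info("simulating study")
        cells, meta, _truth = simulate_study(sim_config)
        _write(cells, outdir, "cells.csv", outputs)
        _write(meta, outdir, "metadata.csv", outputs)

    def stage(name, fn, *args, **kwargs):
        t = time.time()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", name, time.time() - t)
        return result

    abund = stage("abundance", tabulate_abundance, cells, meta)
    alpha = stage("alpha_diversity", diversity.alpha_diversity, abund)
    beta = stage("beta_diversity", diversity.beta_to_control, abund, meta,
                 config.control_treatment)
    alpha_tests = stage("alpha_tests", diversity.compare_groups_alpha, alpha, meta)
    _write(alpha, outdir, "alpha.csv", outputs)
    _write(beta, outdir, "beta.csv", outputs)
    _write(alpha_tests, outdir, "alpha_tests.csv", outputs)

    pairs = stage("pair_counts", coloc.count_pairs, cells, config.radius_um)
    scores = stage("coloc_scores", coloc.colocalization_score, pairs, abund)
    comparisons = stage("coloc_comparisons", coloc.compare_to_control, scores, meta,
                        config.control_treatment, config.signif_alpha,
                        config.effsize_alpha, config.effsize_large)
    summary = stage("stratum_summary", coloc.summarize_strata, comparisons,
                    config.signif_alpha)
    filtered, kept = stage("heatmap_filter", coloc.heatmap_filter, comparisons, abund,
                           config.min_total_count, config.min_prevalence,
                           config.log2fc_threshold, config.signif_alpha,
                           config.recovery_day)
    nets = []
    for (tissue, treatment), _ in filtered.groupby(["tissue", "treatment"]):
        edges = coloc.build_network(filtered, tissue, treatment, config.recovery_day)
        edges.insert(0, "tissue", tissue)
        edges.insert(1, "treatment", treatment)
        nets.append(edges)
    network = pd.concat(nets, ignore_index=True) if nets else pd.DataFrame(
        columns=["tissue", "treatment", "taxon_a", "taxon_b", "weight", "sign"])
    _write(scores, outdir, "coloc_scores.csv", outputs)
    _write(comparisons, outdir, "coloc_comparisons.csv", outputs)
    _write(summary, outdir, "stratum_summary.csv", outputs)
    _write(filtered, outdir, "heatmap_pairs.csv", outputs)
    _write(network, outdir, "network_edges.csv", outputs)

    baseline_ids = meta.loc[meta["day"] == config.baseline_day, "image_id"]
    r_grid = np.arange(0.0, config.rmax_um + 1e-9, 0.5)
    curves = stage("mark_equality", mark_equality.mark_equality_curves,
                   cells[cells["image_id"].isin(baseline_ids)], r_grid)
    _write(curves, outdir, "markcorr_curves.csv", outputs)
    if curves["image_id"].nunique() >= 2 and meta["tissue"].nunique() >= 1:
        tissue_curves = stage("mark_equality_tissues",
                              mark_equality.compare_tissue_curves, curves, meta,
                              200, 0.95, config.seed)
        _write(tissue_curves, outdir, "markcorr_tissue.csv", outputs)

    raw = stage("neighborhood_counts", neighborhood.neighborhood_counts,
                cells, config.radius_um)
    scored = stage("neighborhood_scores", neighborhood.neighborhood_scores, raw, abund)
    _write(raw.reset_index(), outdir, "neighborhood_raw.csv", outputs)
    _write(scored.reset_index(), outdir, "neighborhood_scores.csv", outputs)

    perm_rows = []
    taxa = sorted(raw.index.get_level_values("center_taxon").unique())
    treatments = [t for t in meta["treatment"].unique() if t != config.control_treatment]
    for tissue in meta["tissue"].unique():
        for treatment in treatments:
            for taxon in taxa:
                res = neighborhood.neighborhood_permanova(
                    raw, abund, meta, taxon, tissue, config.recovery_day, treatment,
                    config.control_treatment, n_perm=config.n_perm, seed=config.seed)
                if res is None:
                    continue
                result, coef, top = res
                perm_rows.append((int(taxon), tissue, treatment, result.pseudo_f,
                                  result.p_value, result.method, top))
    permanova_table = pd.DataFrame(perm_rows, columns=[
        "center_taxon", "tissue", "treatment", "pseudo_f", "p_perm", "method",
        "top_driver"])
    _write(permanova_table, outdir, "neighborhood_permanova.csv", outputs)

    per_cell, richness_summary = stage("richness", keystone.neighborhood_richness,
                                       cells, meta, config.radius_um,
                                       config.baseline_day)
    _write(richness_summary, outdir, "richness_summary.csv", outputs)
    rec_parts, call_parts, trend_rows = [], [], []
    for tissue in meta["tissue"].unique():
        for treatment in meta["treatment"].unique():
            try:
                rec = keystone.recovery_correlation(abund, meta, tissue, treatment,
                                                    config.baseline_day,
                                                    config.recovery_day)
            except ValueError:
                continue
            rec_parts.append(rec)
            r, p, n = keystone.richness_recovery_trend(richness_summary, rec,
                                                       tissue, treatment)
            trend_rows.append((tissue, treatment, r, p, n))
            calls = keystone.call_keystones(
                richness_summary, rec, tissue, treatment,
                config.richness_percentile, config.abundance_percentile,
                config.correlation_percentile)
            calls.insert(0, "tissue", tissue)
            calls.insert(1, "treatment", treatment)
            call_parts.append(calls)
    if rec_parts:
        _write(pd.concat(rec_parts, ignore_index=True), outdir, "recovery.csv", outputs)
        _write(pd.DataFrame(trend_rows, columns=["tissue", "treatment", "pearson_r",
                                                 "p_value", "n_taxa"]),
               outdir, "trend.csv", outputs)
        _write(pd.concat(call_parts, ignore_index=True), outdir,
               "keystone_calls.csv", outputs)

    manifest = {
        "config": dataclasses.asdict(config),
        "sim_config": config_to_dict(sim_config) if sim_config is not None else None,
        "seed": config.seed,
        "versions": _versions(),
        "n_images": int(meta["image_id"].nunique()),
        "n_cells": int(len(cells)),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": outputs,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
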