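"""Keystone and foundation species screen.

Three ingredients, computed at baseline and over recovery:

1. Neighborhood richness: for every baseline cell, the number of unique
   taxa among its neighbors within 5 µm (the center cell excluded,
   conspecific neighbors counted as one species). Summarized per center
   taxon (and tissue) as the mean over cells.
2. Recovery correlation: per taxon and (tissue, treatment), the Pearson
   correlation across all (baseline image, recovery image) pairs between
   the taxon's relative abundance at baseline and the recovery of the
   pair, 1 - Bray-Curtis between the two images (computed on
   proportions, so recovery measures compositional return rather than
   load). In the unperturbed control group this same quantity measures
   community stability.
3. Richness-recovery trend: Pearson correlation across taxa between mean
   neighborhood richness and the recovery correlation coefficient,
   restricted to significant recovery correlations.

Keystone call: richness percentile >= 75, abundance percentile <= 80
(not in the top 20%), recovery-correlation percentile >= 75. Foundation
call: abundance in the top quintile and richness percentile >= 75.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import braycurtis

__all__ = [
    "neighborhood_richness",
    "recovery_correlation",
    "richness_recovery_trend",
    "call_keystones",
]


def neighborhood_richness(
    cells: pd.DataFrame,
    meta: pd.DataFrame,
    r_um: float = 5.0,
    baseline_day: int = -8,
    include_conspecific: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell neighborhood richness on baseline images.

    Returns (per_cell, summary): per_cell has one row per baseline cell
    (image_id, tissue, center_taxon, richness); summary aggregates per
    (tissue, center_taxon) with mean_richness, n_cells, and
    log_mean_abundance (natural log of the taxon's mean per-image count
    at baseline in that tissue).
    """
    base_meta = meta[meta["day"] == baseline_day]
    tissue_of = dict(zip(base_meta["image_id"], base_meta["tissue"]))
    base_cells = cells[cells["image_id"].isin(tissue_of)]
    rows = []
    for image_id, img in base_cells.groupby("image_id", sort=True):
        xy = img[["x_um", "y_um"]].to_numpy(dtype=float)
        taxa = img["taxon_id"].to_numpy()
        tissue = tissue_of[image_id]
        neighbor_sets: list[set[int]] = [set() for _ in range(len(img))]
        if len(img) >= 2:
            for i, j in cKDTree(xy).query_pairs(r_um):
                a, b = int(taxa[i]), int(taxa[j])
                if include_conspecific or a != b:
                    neighbor_sets[i].add(b)
                    neighbor_sets[j].add(a)
        for i in range(len(img)):
            rows.append((image_id, tissue, int(taxa[i]), len(neighbor_sets[i])))
    per_cell = pd.DataFrame(rows, columns=["image_id", "tissue", "center_taxon", "richness"])

    # mean per-image baseline count per taxon and tissue, for the
    # abundance coloring / foundation screen
    img_counts = (base_cells.groupby(["image_id", "taxon_id"]).size()
                  .rename("count").reset_index())
    img_counts["tissue"] = img_counts["image_id"].map(tissue_of)
    n_images = base_meta.groupby("tissue")["image_id"].nunique()
    summaries = []
    for (tissue, taxon), g in per_cell.groupby(["tissue", "center_taxon"]):
        total = img_counts.loc[(img_counts["tissue"] == tissue)
                               & (img_counts["taxon_id"] == taxon), "count"].sum()
        mean_abund = total / n_images[tissue]
        summaries.append((tissue, taxon, float(g["richness"].mean()), len(g),
                          float(np.log(mean_abund)) if mean_abund > 0 else np.nan))
    summary = pd.DataFrame(summaries, columns=[
        "tissue", "center_taxon", "mean_richness", "n_cells", "log_mean_abundance"])
    return per_cell, summary


def recovery_correlation(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    treatment: str,
    baseline_day: int = -8,
    recovery_day: int = 35,
    proportions: bool = True,
) -> pd.DataFrame:
    """Per-taxon correlation of baseline abundance with recovery.

    For every (baseline image i, recovery image j) cross-pair in the
    stratum, x = the taxon's relative abundance in i and
    y = 1 - Bray-Curtis(i, j). Returns pearson_r, p_value, n_pairs per
    taxon; taxa absent from every baseline image are skipped, taxa with
    zero variance across baseline images are flagged with no r.
    """
    sel = meta[(meta["tissue"] == tissue) & (meta["treatment"] == treatment)]
    base = sel.loc[sel["day"] == baseline_day, "image_id"].tolist()
    recov = sel.loc[sel["day"] == recovery_day, "image_id"].tolist()
    if len(base) < 2 or len(recov) < 2:
        raise ValueError("need at least two baseline and two recovery images")
    mat = abund.loc[base + recov].to_numpy(dtype=float)
    if proportions:
        totals = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, totals, out=np.zeros_like(mat), where=totals > 0)
    comp = pd.DataFrame(mat, index=base + recov, columns=abund.columns)
    rec = np.array([[1.0 - braycurtis(comp.loc[i], comp.loc[j]) for j in recov]
                    for i in base])
    y = rec.ravel()
    rows = []
    for taxon in abund.columns:
        x_base = comp.loc[base, taxon].to_numpy()
        if x_base.sum() == 0:
            continue
        x = np.repeat(x_base, len(recov))
        if np.std(x_base) == 0:
            rows.append((int(taxon), tissue, treatment, np.nan, np.nan, len(y), True))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((int(taxon), tissue, treatment, float(r), float(p), len(y), False))
    return pd.DataFrame(rows, columns=["taxon_id", "tissue", "treatment",
                                       "pearson_r", "p_value", "n_pairs", "degenerate"])


def richness_recovery_trend(
    richness_summary: pd.DataFrame,
    recovery: pd.DataFrame,
    tissue: str,
    treatment: str,
    p_threshold: float = 0.05,
    require_significant: bool = True,
) -> tuple[float, float, int]:
    """Across-taxon trend: mean neighborhood richness vs recovery correlation.

    Only taxa whose recovery correlation is significant (p below the
    threshold) contribute when ``require_significant``. Returns
    (pearson_r, p, n_taxa); (nan, nan, n) when fewer than three taxa
    remain or richness has no variance.
    """
    rich = richness_summary[richness_summary["tissue"] == tissue]
    rec = recovery[(recovery["tissue"] == tissue) & (recovery["treatment"] == treatment)]
    rec = rec.dropna(subset=["pearson_r"])
    if require_significant:
        rec = rec[rec["p_value"] < p_threshold]
    merged = rich.merge(rec, left_on="center_taxon", right_on="taxon_id")
    n = len(merged)
    if n < 3 or merged["mean_richness"].std() == 0 or merged["pearson_r"].std() == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(merged["mean_richness"], merged["pearson_r"])
    return float(r), float(p), n


def _percentile_rank(values: pd.Series) -> pd.Series:
    """Percentile rank in (0, 100], mean rank for ties."""
    return values.rank(pct=True) * 100.0


def call_keystones(
    richness_summary: pd.DataFrame,
    recovery: pd.DataFrame,
    tissue: str,
    treatment: str,
    richness_percentile: float = 75.0,
    abundance_percentile: float = 80.0,
    correlation_percentile: float = 75.0,
    foundation_abundance_percentile: float = 80.0,
) -> pd.DataFrame:
    """Percentile-based keystone / foundation calls for one stratum.

    keystone: richness pctl >= 75, abundance pctl <= 80, recovery-
    correlation pctl >= 75. foundation: abundance pctl >= 80 (top
    quintile) and richness pctl >= 75. Degenerate screens (a quantity
    identical across all taxa) yield no calls on that axis and a
    ``degenerate`` flag.
    """
    rich = richness_summary[richness_summary["tissue"] == tissue].set_index("center_taxon")
    rec = recovery[(recovery["tissue"] == tissue)
                   & (recovery["treatment"] == treatment)].set_index("taxon_id")
    taxa = sorted(set(rich.index) & set(rec.index))
    df = pd.DataFrame({
        "taxon_id": taxa,
        "mean_richness": [rich.loc[t, "mean_richness"] for t in taxa],
        "log_mean_abundance": [rich.loc[t, "log_mean_abundance"] for t in taxa],
        "pearson_r": [rec.loc[t, "pearson_r"] for t in taxa],
    })
    degenerate = (df["mean_richness"].nunique() <= 1
                  or df["log_mean_abundance"].nunique() <= 1
                  or df["pearson_r"].nunique(dropna=False) <= 1)
    df["richness_percentile"] = _percentile_rank(df["mean_richness"])
    df["abundance_percentile"] = _percentile_rank(df["log_mean_abundance"])
    df["correlation_percentile"] = _percentile_rank(df["pearson_r"])
    df["degenerate"] = degenerate

    def classify(row) -> str:
        if degenerate:
            return "none"
        if (row["abundance_percentile"] >= foundation_abundance_percentile
                and row["richness_percentile"] >= richness_percentile):
            return "foundation"
        if (row["richness_percentile"] >= richness_percentile
                and row["abundance_percentile"] <= abundance_percentile
                and row["correlation_percentile"] >= correlation_percentile):
            return "keystone"
        return "none"

    df["class"] = df.apply(classify, axis=1)
    return df
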