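"""Fixed-radius pairwise colocalization analysis (tier 2).

Every ordered pair of distinct cells whose centroids lie within a radius
r (default 5 µm) is counted per image and taxon pair. The colocalization
score of a taxon pair (A, B) in an image is

    CS = P(AB) / (P(A) * P(B))

where P(AB) is the proportion of ordered within-radius pairs of type
(A, B) and P(A), P(B) are the taxa's relative abundances in the image.
CS is 1 when the two taxa colocalize exactly as often as expected under
independence, > 1 for attraction, < 1 for avoidance. Ordered-pair
counting makes the independence expectation exactly P(A)P(B), with no
factor-of-2 correction; since CS(A,B) = CS(B,A), results are reported on
unordered pairs.

Treatment-vs-control comparisons use the Kruskal-Wallis test over
per-image scores with Benjamini-Hochberg adjustment, the eta-squared
effect size (H - k + 1)/(n - k), and log2 fold changes of group mean
scores. Filtering for the study-wide heatmap and network export follows
the count/prevalence/log2FC/significance rules.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "count_pairs",
    "colocalization_score",
    "compare_to_control",
    "summarize_strata",
    "percent",
    "kw_effect_size",
    "heatmap_filter",
    "build_network",
]

# smallest positive surrogate for a zero group mean in log2 fold changes;
# such rows carry fold_change_flag
_ZERO_MEAN_SURROGATE = np.finfo(float).tiny


def count_pairs(cells: pd.DataFrame, r_um: float = 5.0) -> pd.DataFrame:
    """Count ordered within-radius cell pairs per image and taxon pair.

    Distance is the closed ball (<= r) on centroids; no edge correction
    (each FoV is the observed region). An image with fewer than two
    cells contributes no rows.
    """
    if r_um <= 0:
        raise ValueError("r_um must be positive")
    rows = []
    for image_id, img in cells.groupby("image_id", sort=True):
        if len(img) < 2:
            continue
        xy = img[["x_um", "y_um"]].to_numpy(dtype=float)
        taxa = img["taxon_id"].to_numpy()
        tally: Counter = Counter()
        for i, j in cKDTree(xy).query_pairs(r_um):
            a, b = taxa[i], taxa[j]
            tally[(a, b)] += 1
            tally[(b, a)] += 1
        for (a, b), c in sorted(tally.items()):
            rows.append((image_id, int(a), int(b), int(c), r_um))
    return pd.DataFrame(rows, columns=["image_id", "taxon_a", "taxon_b",
                                       "ordered_pair_count", "r_um"])


def colocalization_score(
    pairs: pd.DataFrame,
    abund: pd.DataFrame,
    dense: bool = True,
    denominator: str = "neighbor_pairs",
) -> pd.DataFrame:
    """Colocalization scores per image and unordered taxon pair.

    P(AB) uses all ordered within-radius pairs of the image as the
    denominator (``denominator="neighbor_pairs"``, which gives CS = 1
    under independence); ``"all_pairs"`` instead divides by n(n-1), all
    ordered pairs in the image. With ``dense=True`` every unordered pair
    of taxa present in the image is emitted (score 0 when no neighbor
    pairs of that type exist); otherwise only observed pairs. Scores are
    missing (never infinite) where P(A)P(B) = 0 or the image has no
    neighbor pairs.
    """
    if denominator not in ("neighbor_pairs", "all_pairs"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    counts = abund.to_numpy(dtype=float)
    n_img = counts.sum(axis=1)
    rows = []
    pair_groups = dict(tuple(pairs.groupby("image_id")))
    for i, image_id in enumerate(abund.index):
        if n_img[i] == 0:
            continue
        p = counts[i] / n_img[i]
        present = [int(t) for t, c in zip(abund.columns, counts[i]) if c > 0]
        col_of = {int(t): k for k, t in enumerate(abund.columns)}
        img_pairs = pair_groups.get(image_id)
        tally: dict[tuple[int, int], int] = {}
        total_ordered = 0
        if img_pairs is not None:
            for a, b, c in img_pairs[["taxon_a", "taxon_b", "ordered_pair_count"]].itertuples(index=False):
                tally[(int(a), int(b))] = int(c)
                total_ordered += int(c)
        if denominator == "all_pairs":
            denom_pairs = n_img[i] * (n_img[i] - 1)
        else:
            denom_pairs = total_ordered
        if dense:
            iter_pairs = [(a, b) for ai, a in enumerate(present) for b in present[ai:]]
        else:
            iter_pairs = sorted({(min(a, b), max(a, b)) for a, b in tally})
        for a, b in iter_pairs:
            p_a, p_b = p[col_of[a]], p[col_of[b]]
            c_ab = tally.get((a, b), 0)
            if denom_pairs == 0 or p_a * p_b == 0:
                cs = np.nan
                p_ab = np.nan
            else:
                p_ab = c_ab / denom_pairs
                cs = p_ab / (p_a * p_b)
            rows.append((image_id, a, b, cs, p_ab, p_a, p_b))
    return pd.DataFrame(rows, columns=["image_id", "taxon_a", "taxon_b",
                                       "cs", "p_ab", "p_a", "p_b"])


def kw_effect_size(h_stat: float, k: int, n: int) -> float:
    """Eta-squared effect size for the Kruskal-Wallis H statistic."""
    if n <= k:
        return np.nan
    return float((h_stat - k + 1) / (n - k))


def compare_to_control(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    control_treatment: str = "water",
    signif_alpha: float = 0.05,
    effsize_alpha: float = 0.1,
    effsize_large: float = 0.14,
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of per-image CS against the control group.

    One row per (tissue, day, treatment != control, unordered pair) with
    the pair scored (non-missing) in >= 2 images of both groups. BH
    adjustment is applied within each (tissue, day, treatment) family.
    Effect sizes are computed only for pairs with p_adj < effsize_alpha.
    log2 fold change is of group means of CS; a zero mean is replaced by
    the smallest positive float and flagged.
    """
    merged = scores.merge(meta[["image_id", "tissue", "treatment", "day"]], on="image_id")
    merged = merged.dropna(subset=["cs"])
    out = []
    for (tissue, day), sub in merged.groupby(["tissue", "day"]):
        ctrl = sub[sub["treatment"] == control_treatment]
        ctrl_groups = {k: v["cs"].to_numpy() for k, v in ctrl.groupby(["taxon_a", "taxon_b"])}
        for treatment, tsub in sub.groupby("treatment"):
            if treatment == control_treatment:
                continue
            fam = []
            for (a, b), g in tsub.groupby(["taxon_a", "taxon_b"]):
                x = g["cs"].to_numpy()
                y = ctrl_groups.get((a, b))
                if y is None or len(x) < 2 or len(y) < 2:
                    continue
                if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                    h, p = 0.0, 1.0
                else:
                    h, p = stats.kruskal(x, y)
                mx, my = float(np.mean(x)), float(np.mean(y))
                flag = mx == 0 or my == 0
                l2fc = float(np.log2(max(mx, _ZERO_MEAN_SURROGATE)
                                     / max(my, _ZERO_MEAN_SURROGATE)))
                fam.append([tissue, day, treatment, int(a), int(b), len(x), len(y),
                            float(h), float(p), l2fc, flag])
            if not fam:
                continue
            p_adj = multipletests([r[8] for r in fam], method="fdr_bh")[1]
            for r, pa in zip(fam, p_adj):
                n = r[5] + r[6]
                eff = kw_effect_size(r[7], 2, n) if pa < effsize_alpha else np.nan
                large = bool(not np.isnan(eff) and eff >= effsize_large)
                out.append(r + [float(pa), eff, large])
    return pd.DataFrame(out, columns=[
        "tissue", "day", "treatment", "taxon_a", "taxon_b", "n_treat", "n_control",
        "h_stat", "p_kw", "log2fc", "fold_change_flag", "p_adj", "effsize", "large"])


def percent(count: float, total: float) -> float:
    """100 * count / total, rounded to two decimals (NaN when total = 0)."""
    if total == 0:
        return np.nan
    return round(100.0 * count / total, 2)


def summarize_strata(comparisons: pd.DataFrame,
                     signif_alpha: float = 0.05) -> pd.DataFrame:
    """Per-stratum summary: tested pairs, significant, large effects, percents."""
    rows = []
    for (tissue, treatment, day), sub in comparisons.groupby(["tissue", "treatment", "day"]):
        total = len(sub)
        signif = int((sub["p_adj"] < signif_alpha).sum())
        large = int(sub["large"].sum())
        rows.append((tissue, treatment, day, signif, large, total,
                     percent(signif, total), percent(large, total)))
    return pd.DataFrame(rows, columns=[
        "tissue", "treatment", "day", "signif", "large_effectsize",
        "total_colocs", "pct_signif", "pct_large_effsize"])


def heatmap_filter(
    comparisons: pd.DataFrame,
    abund: pd.DataFrame,
    min_total_count: int = 2000,
    min_prevalence: float = 0.25,
    log2fc_threshold: float = 1.0,
    signif_alpha: float = 0.05,
    day: int | None = None,
) -> tuple[pd.DataFrame, set[tuple[int, int]]]:
    """Filter comparison rows for the study-wide heatmap.

    A pair is retained iff both taxa pass the study-wide abundance filter
    (total count >= ``min_total_count`` and present in at least
    ``min_prevalence`` of images), |log2FC| exceeds the threshold in at
    least one stratum, and the pair is significant in at least one
    stratum. Returns the retained long table and the retained pair set.
    """
    totals = abund.sum(axis=0)
    prevalence = (abund > 0).mean(axis=0)
    passing = {int(t) for t in abund.columns
               if totals[t] >= min_total_count and prevalence[t] >= min_prevalence}
    comp = comparisons if day is None else comparisons[comparisons["day"] == day]
    # rows whose fold change is undefined (a zero group mean) carry a
    # surrogate log2fc and are excluded from heatmap and network export
    comp = comp[~comp["fold_change_flag"]]
    keep_pairs = set()
    for (a, b), g in comp.groupby(["taxon_a", "taxon_b"]):
        if a not in passing or b not in passing:
            continue
        if ((g["log2fc"].abs() > log2fc_threshold)).any() and (g["p_adj"] < signif_alpha).any():
            keep_pairs.add((int(a), int(b)))
    mask = comp.apply(lambda r: (int(r["taxon_a"]), int(r["taxon_b"])) in keep_pairs, axis=1)
    filtered = comp[mask].copy() if len(comp) else comp.copy()
    filtered["pair"] = [f"{a}_{b}" for a, b in zip(filtered["taxon_a"], filtered["taxon_b"])]
    return filtered.reset_index(drop=True), keep_pairs


def build_network(filtered: pd.DataFrame, tissue: str, treatment: str,
                  day: int | None = None) -> pd.DataFrame:
    """Undirected edge list for one stratum's interaction-change network.

    Nodes are taxa; edge weight |log2FC|, sign the direction of change.
    Self-interactions are removed.
    """
    sub = filtered[(filtered["tissue"] == tissue) & (filtered["treatment"] == treatment)]
    if day is not None:
        sub = sub[sub["day"] == day]
    sub = sub[sub["taxon_a"] != sub["taxon_b"]]
    rows = []
    for (a, b), g in sub.groupby(["taxon_a", "taxon_b"]):
        l2fc = float(g["log2fc"].iloc[g["log2fc"].abs().argmax()])
        rows.append((int(min(a, b)), int(max(a, b)), abs(l2fc), float(np.sign(l2fc))))
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "weight", "sign"])
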