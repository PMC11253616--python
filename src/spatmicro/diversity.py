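"""Image-level alpha and beta diversity and group comparisons (tier 1).

Alpha diversity per field of view: cell count, richness, Shannon entropy
(natural log by default) and Gini-Simpson index 1 - sum(p_i^2). Beta
diversity: Bray-Curtis dissimilarity between images, in particular each
treatment image against every water-control image within the same
tissue and day. Group comparisons use the two-sample Wilcoxon rank-sum
test with Holm adjustment by default.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from statsmodels.stats.multitest import multipletests

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "beta_to_control",
    "compare_groups_alpha",
    "log_transform_counts",
]


def alpha_diversity(abund: pd.DataFrame, base: float = np.e) -> pd.DataFrame:
    """Per-image alpha diversity from an AbundanceMatrix.

    Empty images get richness 0 and missing Shannon/Simpson values.
    Raises ``ValueError`` on negative counts.
    """
    if (abund.to_numpy() < 0).any():
        raise ValueError("abundance matrix contains negative counts")
    counts = abund.to_numpy(dtype=float)
    n = counts.sum(axis=1)
    rows = []
    for i, image_id in enumerate(abund.index):
        if n[i] == 0:
            rows.append((image_id, 0, 0, np.nan, np.nan))
            continue
        p = counts[i] / n[i]
        p = p[p > 0]
        shannon = float(-(p * np.log(p)).sum() / np.log(base))
        simpson = float(1.0 - (p**2).sum())
        rows.append((image_id, int(n[i]), int((counts[i] > 0).sum()), shannon, simpson))
    return pd.DataFrame(rows, columns=["image_id", "n_cells", "richness", "shannon", "simpson"])


def bray_curtis(abund: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Bray-Curtis dissimilarity for the requested image pairs (raw counts).

    A pair of two empty images yields a missing value. Unknown image ids
    raise ``KeyError``.
    """
    out = []
    for a, b in pairs:
        x = abund.loc[a].to_numpy(dtype=float)
        y = abund.loc[b].to_numpy(dtype=float)
        denom = (x + y).sum()
        bc = np.nan if denom == 0 else float(braycurtis(x, y))
        out.append((a, b, bc))
    return pd.DataFrame(out, columns=["image_id_1", "image_id_2", "bray_curtis"])


def beta_to_control(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    control_treatment: str = "water",
) -> pd.DataFrame:
    """Cross-pair Bray-Curtis of every image against control images.

    Within each (tissue, day): every image of each treatment (including
    the control itself, giving the within-group dispersion) is paired
    with every control image, excluding self-pairs.
    """
    rows = []
    for (tissue, day), sub in meta.groupby(["tissue", "day"]):
        ctrl = sub.loc[sub["treatment"] == control_treatment, "image_id"].tolist()
        if not ctrl:
            continue
        for treatment, tsub in sub.groupby("treatment"):
            pairs = [(i, j) for i in tsub["image_id"] for j in ctrl if i != j]
            if not pairs:
                continue
            bc = bray_curtis(abund, pairs)
            bc["tissue"], bc["day"], bc["treatment"] = tissue, day, treatment
            bc["comparison_label"] = f"{treatment}-vs-{control_treatment}"
            rows.append(bc)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["image_id_1", "image_id_2", "bray_curtis", "tissue", "day",
                 "treatment", "comparison_label"])


def compare_groups_alpha(
    alpha: pd.DataFrame,
    meta: pd.DataFrame,
    metric: str = "shannon",
    adjust: str = "holm",
) -> pd.DataFrame:
    """Pairwise treatment comparisons of an alpha metric within tissue x day.

    Two-sample Wilcoxon rank-sum per treatment pair; adjustment (Holm by
    default) applied within each tissue x day family. Degenerate groups
    (n < 2 or all values tied across both groups) are flagged with no
    p-value.
    """
    merged = alpha.merge(meta, on="image_id")
    rows = []
    for (tissue, day), sub in merged.groupby(["tissue", "day"]):
        fam = []
        for t1, t2 in itertools.combinations(sorted(sub["treatment"].unique()), 2):
            x = sub.loc[sub["treatment"] == t1, metric].dropna().to_numpy()
            y = sub.loc[sub["treatment"] == t2, metric].dropna().to_numpy()
            degenerate = (len(x) < 2 or len(y) < 2
                          or len(np.unique(np.concatenate([x, y]))) == 1)
            if degenerate:
                fam.append([tissue, day, t1, t2, len(x), len(y), np.nan, np.nan, 0.0, True])
                continue
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            direction = float(np.sign(np.median(x) - np.median(y)))
            fam.append([tissue, day, t1, t2, len(x), len(y), float(stat), float(p),
                        direction, False])
        pvals = [r[7] for r in fam if not r[9]]
        if pvals:
            adj = multipletests(pvals, method=adjust)[1]
            it = iter(adj)
            for r in fam:
                r.append(np.nan if r[9] else float(next(it)))
        else:
            for r in fam:
                r.append(np.nan)
        rows.extend(fam)
    return pd.DataFrame(rows, columns=[
        "tissue", "day", "treatment_1", "treatment_2", "n_1", "n_2",
        "statistic", "p_value", "direction", "degenerate", "p_adj"])


def log_transform_counts(abund: pd.DataFrame) -> pd.DataFrame:
    """log(count + 1) transform used before ordination of image counts."""
    return np.log1p(abund.astype(float))
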