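"""Center-bug neighborhood analysis (tier 3).

For every cell ("center bug") the cells within a fixed radius (default
5 µm) form its neighborhood. Per image and center taxon y, neighbor
counts are pooled over all cells of y, giving a composition row. The
neighborhood colocalization score of neighbor taxon x in y's
neighborhoods is

    N_yx = xy_c / (x_p * ny_c)

where xy_c is the count of x among y's neighbors, x_p the image-level
proportion of x, and ny_c the total neighbor count in y's
neighborhoods; > 1 means x occurs in y's neighborhood more often than
its abundance predicts.

Group differences in a center taxon's neighborhood composition are
tested with a one-factor PERMANOVA on Bray-Curtis distances (999 label
permutations by default, exhaustive enumeration when the design is
small enough), with per-neighbor-taxon coefficients (difference of
group means) identifying the taxon driving the change. Ordination is
by nonmetric MDS (with species vectors) or UMAP.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "neighborhood_counts",
    "neighborhood_scores",
    "PermanovaResult",
    "permanova",
    "neighborhood_permanova",
    "nmds",
    "ordinate_neighborhoods",
]


def neighborhood_counts(cells: pd.DataFrame, r_um: float = 5.0,
                        include_conspecific: bool = True) -> pd.DataFrame:
    """Raw neighborhood count matrix.

    Wide DataFrame indexed by (image_id, center_taxon), columns =
    neighbor taxon ids, entries = neighbors of that taxon within r of
    any center cell, pooled per image. The center cell never counts
    itself; other cells of the center taxon count as neighbors unless
    ``include_conspecific`` is False. Taxa present in an image always
    get a row, even when all their cells are isolated (all-zero row).
    """
    if r_um <= 0:
        raise ValueError("r_um must be positive")
    all_taxa = sorted(set(cells["taxon_id"].astype(int)))
    index_rows: list[tuple[str, int]] = []
    data: dict[tuple[str, int], Counter] = {}
    for image_id, img in cells.groupby("image_id", sort=True):
        taxa = img["taxon_id"].to_numpy()
        for t in sorted(set(int(t) for t in taxa)):
            index_rows.append((image_id, t))
            data[(image_id, t)] = Counter()
        if len(img) < 2:
            continue
        xy = img[["x_um", "y_um"]].to_numpy(dtype=float)
        for i, j in cKDTree(xy).query_pairs(r_um):
            a, b = int(taxa[i]), int(taxa[j])
            if not include_conspecific and a == b:
                continue
            data[(image_id, a)][b] += 1
            data[(image_id, b)][a] += 1
    mat = pd.DataFrame(
        [[data[key].get(x, 0) for x in all_taxa] for key in index_rows],
        index=pd.MultiIndex.from_tuples(index_rows, names=["image_id", "center_taxon"]),
        columns=pd.Index(all_taxa, name="neighbor_taxon"),
        dtype=np.int64,
    )
    return mat


def neighborhood_scores(raw: pd.DataFrame, abund: pd.DataFrame) -> pd.DataFrame:
    """Neighborhood colocalization scores N_yx = xy_c / (x_p * ny_c).

    Rows with no neighbors (ny_c = 0) and columns for taxa absent from
    the image get missing scores.
    """
    counts = abund.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    prop = pd.DataFrame(
        np.divide(counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0),
        index=abund.index, columns=[int(c) for c in abund.columns])
    out = np.full(raw.shape, np.nan)
    raw_np = raw.to_numpy(dtype=float)
    ny_c = raw_np.sum(axis=1)
    for i, (image_id, _y) in enumerate(raw.index):
        if ny_c[i] == 0:
            continue
        for j, x in enumerate(raw.columns):
            xp = float(prop.loc[image_id, int(x)]) if int(x) in prop.columns else 0.0
            if xp == 0:
                assert raw_np[i, j] == 0, "neighbor of a taxon absent from the image"
                continue
            out[i, j] = raw_np[i, j] / (xp * ny_c[i])
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


# ------------------------------------------------------------- PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "permutation" or "exhaustive"
    ss_among: float
    ss_within: float


def _pseudo_f(dm2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Pseudo-F from a squared-distance matrix and group labels.

    Uses the distance-based sum-of-squares partition: total SS is the
    mean of squared distances over all pairs; within SS sums the same
    quantity per group.
    """
    n = len(labels)
    groups = np.unique(labels)
    k = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = dm2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = dm2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_within <= 0 or n <= k:
        return np.inf if ss_among > 0 else 0.0, ss_among, ss_within
    f = (ss_among / (k - 1)) / (ss_within / (n - k))
    return float(f), float(ss_among), float(ss_within)


def permanova(dm: np.ndarray, labels, n_perm: int = 999, seed: int = 0,
              exhaustive: str = "auto") -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``p = (b + 1) / (n_perm + 1)`` where b counts permutations with
    pseudo-F >= observed. When the number of distinct label arrangements
    is at most ``n_perm`` (and ``exhaustive`` is not "never"), all
    arrangements are enumerated instead and p is the exact fraction with
    pseudo-F >= observed (the identity arrangement included).
    """
    labels = np.asarray(labels)
    dm = np.asarray(dm, dtype=float)
    dm2 = dm**2
    f_obs, ss_a, ss_w = _pseudo_f(dm2, labels)

    groups, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    n_arrangements = 1
    rem = n
    for c in counts:
        n_arrangements *= comb(rem, int(c))
        rem -= int(c)

    do_exhaustive = exhaustive == "always" or (
        exhaustive == "auto" and n_arrangements <= n_perm)
    if do_exhaustive:
        from sympy.utilities.iterables import multiset_permutations

        hits = total = 0
        for perm in multiset_permutations(list(labels)):
            f_p, _, _ = _pseudo_f(dm2, np.asarray(perm))
            total += 1
            if f_p >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(f_obs, hits / total, total, "exhaustive", ss_a, ss_w)

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        f_p, _, _ = _pseudo_f(dm2, rng.permutation(labels))
        if f_p >= f_obs - 1e-12:
            b += 1
    return PermanovaResult(f_obs, (b + 1) / (n_perm + 1), n_perm, "permutation", ss_a, ss_w)


def _composition_rows(raw: pd.DataFrame, abund: pd.DataFrame, center_taxon: int,
                      image_ids: list[str], on: str) -> pd.DataFrame:
    """Per-image composition rows for one center taxon."""
    sub = raw.xs(center_taxon, level="center_taxon")
    sub = sub.loc[[i for i in image_ids if i in sub.index]]
    sub = sub[sub.sum(axis=1) > 0]
    if on == "counts":
        return sub.astype(float)
    if on == "proportions":
        return sub.div(sub.sum(axis=1), axis=0)
    if on == "scores":
        scored = neighborhood_scores(
            raw.loc[[(i, center_taxon) for i in sub.index]], abund.loc[sub.index])
        return scored.xs(center_taxon, level="center_taxon").fillna(0.0)
    raise ValueError(f"unknown composition mode {on!r}")


def neighborhood_permanova(
    raw: pd.DataFrame,
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    center_taxon: int,
    tissue: str,
    day: int,
    treatment: str,
    control_treatment: str = "water",
    n_perm: int = 999,
    seed: int = 0,
    on: str = "proportions",
) -> tuple[PermanovaResult, pd.Series, int] | None:
    """PERMANOVA of one center taxon's neighborhoods, treatment vs control.

    Rows are per-image neighborhood compositions (proportions by
    default) of the center taxon within (tissue, day). Returns the test
    result, signed per-neighbor-taxon coefficients (treatment group mean
    minus control group mean of the composition), and the top-driver
    taxon; or None when either group has fewer than two images.
    """
    sel = meta[(meta["tissue"] == tissue) & (meta["day"] == day)
               & (meta["treatment"].isin([treatment, control_treatment]))]
    comp = _composition_rows(raw, abund, center_taxon, sel["image_id"].tolist(), on)
    if len(comp) < 4:
        return None
    labels = sel.set_index("image_id").loc[comp.index, "treatment"].to_numpy()
    if min((labels == treatment).sum(), (labels == control_treatment).sum()) < 2:
        return None
    dm = squareform(pdist(comp.to_numpy(), metric="braycurtis"))
    dm = np.nan_to_num(dm, nan=0.0)
    result = permanova(dm, labels, n_perm=n_perm, seed=seed)
    coef = (comp[labels == treatment].mean() - comp[labels == control_treatment].mean())
    top_driver = int(coef.abs().idxmax())
    return result, coef, top_driver


# ------------------------------------------------------------- ordination

def nmds(comp: pd.DataFrame, seed: int = 0, max_iter: int = 300,
         n_init: int = 4) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Nonmetric MDS of composition rows on Bray-Curtis distances.

    Returns (coordinates, Kruskal stress-1, species vectors). Species
    vectors are the correlations of each taxon's values with the two
    axes: direction shows which taxa drive the separation, length the
    strength of the association. Degenerate all-identical rows embed as
    coincident points with stress 0.
    """
    from sklearn.manifold import MDS

    x = comp.to_numpy(dtype=float)
    dm = squareform(pdist(x, metric="braycurtis"))
    dm = np.nan_to_num(dm, nan=0.0)
    if np.allclose(dm, 0):
        coords = np.zeros((len(comp), 2))
        stress = 0.0
    else:
        mds = MDS(n_components=2, metric="precomputed", metric_mds=False,
                  random_state=seed, max_iter=max_iter, n_init=n_init,
                  init="random", normalized_stress=True)
        coords = mds.fit_transform(dm)
        stress = float(mds.stress_)
    coord_df = pd.DataFrame(coords, index=comp.index, columns=["axis_1", "axis_2"])
    vecs = []
    for taxon in comp.columns:
        v = x[:, list(comp.columns).index(taxon)]
        if np.std(v) == 0 or np.allclose(coords.std(axis=0), 0):
            vecs.append((taxon, 0.0, 0.0))
            continue
        r1 = float(np.corrcoef(v, coords[:, 0])[0, 1]) if coords[:, 0].std() > 0 else 0.0
        r2 = float(np.corrcoef(v, coords[:, 1])[0, 1]) if coords[:, 1].std() > 0 else 0.0
        vecs.append((taxon, r1, r2))
    vec_df = pd.DataFrame(vecs, columns=["taxon_id", "axis_1", "axis_2"])
    return coord_df, stress, vec_df


def ordinate_neighborhoods(comp: pd.DataFrame, method: str = "nmds",
                           seed: int = 0, n_neighbors: int = 10):
    """2-D embedding of neighborhood composition rows.

    ``method="nmds"`` returns (coords, stress, species_vectors);
    ``method="umap"`` returns coords only (n_neighbors = 10 by default,
    deterministic under the seed).
    """
    if len(comp) < 3:
        raise ValueError("ordination requires at least three rows")
    if method == "nmds":
        return nmds(comp, seed=seed)
    if method == "umap":
        import warnings

        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = umap.UMAP(n_neighbors=min(n_neighbors, len(comp) - 1),
                            random_state=seed).fit_transform(comp.to_numpy(dtype=float))
        return pd.DataFrame(emb, index=comp.index, columns=["umap_1", "umap_2"])
    raise ValueError(f"unknown ordination method {method!r}")
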