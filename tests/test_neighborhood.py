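import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spatmicro import neighborhood as nb

from conftest import make_cells, make_meta


def brute_neighborhood_counts(xy, taxa, r):
    """O(n^2) oracle: per center taxon, summed neighbor-taxon counts."""
    out = {}
    n = len(xy)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= r:
                key = (int(taxa[i]), int(taxa[j]))
                out[key] = out.get(key, 0) + 1
    return out


def gower_pseudo_f(dm, labels):
    """Independent PERMANOVA pseudo-F via the centered Gower matrix and
    the hat-matrix projection (a different algebraic route than the
    per-group sum-of-squares used by the implementation)."""
    n = len(labels)
    a = -0.5 * dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    x = pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    k = x.shape[1]
    ss_among = np.trace(h @ g @ h)
    ss_resid = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
    return (ss_among / (k - 1)) / (ss_resid / (n - k))


class TestCounts:
    def test_two_cells_mutual_neighbors(self):
        cells = make_cells([(0, 0), (3, 0)], [0, 1])
        raw = nb.neighborhood_counts(cells, 5.0)
        assert raw.loc[("img1", 0), 1] == 1
        assert raw.loc[("img1", 1), 0] == 1

    def test_isolated_cell_zero_row(self):
        cells = make_cells([(0, 0), (50, 50)], [0, 1])
        raw = nb.neighborhood_counts(cells, 5.0)
        assert raw.loc[("img1", 0)].sum() == 0
        assert raw.loc[("img1", 1)].sum() == 0

    def test_conspecific_toggle(self):
        cells = make_cells([(0, 0), (1, 0), (2, 0)], [0, 0, 1])
        with_con = nb.neighborhood_counts(cells, 5.0)
        without = nb.neighborhood_counts(cells, 5.0, include_conspecific=False)
        assert with_con.loc[("img1", 0), 0] == 2
        assert without.loc[("img1", 0), 0] == 0
        assert without.loc[("img1", 0), 1] == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 90)
        xy = rng.uniform(0, 40, size=(n, 2))
        taxa = rng.integers(0, 4, size=n)
        raw = nb.neighborhood_counts(make_cells(xy, taxa), 5.0)
        expected = brute_neighborhood_counts(xy, taxa, 5.0)
        for (y, x), c in expected.items():
            assert raw.loc[("img1", y), x] == c
        assert raw.to_numpy().sum() == sum(expected.values())

    def test_row_sum_conservation(self, scaled_study):
        _cfg, cells, _meta, _truth = scaled_study
        one = cells[cells["image_id"] == cells["image_id"].iloc[0]]
        raw = nb.neighborhood_counts(one, 5.0)
        # total ordered neighbor relations = 2 * within-radius pairs
        from scipy.spatial import cKDTree

        xy = one[["x_um", "y_um"]].to_numpy()
        n_pairs = len(cKDTree(xy).query_pairs(5.0))
        assert raw.to_numpy().sum() == 2 * n_pairs


class TestScores:
    def test_direct_formula(self):
        raw = pd.DataFrame(
            [[4, 6]],
            index=pd.MultiIndex.from_tuples([("img1", 1)],
                                            names=["image_id", "center_taxon"]),
            columns=pd.Index([0, 1], name="neighbor_taxon"))
        abund = pd.DataFrame([[4, 16]], index=pd.Index(["img1"], name="image_id"))
        out = nb.neighborhood_scores(raw, abund)
        # xy_c=4, xp=0.2, ny_c=10 -> 4 / (0.2 * 10) = 2.0
        assert out.loc[("img1", 1), 0] == pytest.approx(2.0)

    def test_zero_neighbor_rows_missing(self):
        raw = pd.DataFrame(
            [[0, 0]],
            index=pd.MultiIndex.from_tuples([("img1", 0)],
                                            names=["image_id", "center_taxon"]),
            columns=pd.Index([0, 1], name="neighbor_taxon"))
        abund = pd.DataFrame([[3, 3]], index=pd.Index(["img1"], name="image_id"))
        out = nb.neighborhood_scores(raw, abund)
        assert out.isna().all().all()

    def test_random_labeling_null_centred_on_one(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 80, (150, 2))
        taxa = np.repeat([0, 1, 2], 50)
        abund = pd.DataFrame([[50, 50, 50]], index=pd.Index(["img1"], name="image_id"))
        samples = {}
        for _ in range(200):
            perm = rng.permutation(taxa)
            raw = nb.neighborhood_counts(make_cells(xy, perm), 5.0)
            scored = nb.neighborhood_scores(raw, abund)
            for (_img, y, x), v in scored.stack().items():
                samples.setdefault((y, x), []).append(v)
        for key, vals in samples.items():
            vals = np.asarray(vals)
            sem = vals.std(ddof=1) / math.sqrt(len(vals))
            assert abs(vals.mean() - 1.0) < 3 * sem, key

    def test_recomputation_matches_counts_and_abundance(self, scaled_study):
        _cfg, cells, meta, _truth = scaled_study
        img = meta["image_id"].iloc[0]
        one = cells[cells["image_id"] == img]
        from spatmicro import tabulate_abundance

        abund = tabulate_abundance(one, meta[meta["image_id"] == img])
        raw = nb.neighborhood_counts(one, 5.0)
        scored = nb.neighborhood_scores(raw, abund)
        prop = abund.loc[img] / abund.loc[img].sum()
        for (row_img, y) in raw.index:
            ny_c = raw.loc[(row_img, y)].sum()
            if ny_c == 0:
                continue
            for x in raw.columns:
                expected = raw.loc[(row_img, y), x] / (prop[x] * ny_c)
                assert scored.loc[(row_img, y), x] == pytest.approx(expected)


class TestPermanova:
    def test_three_v_three_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        comp = rng.uniform(0, 1, size=(6, 4))
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(comp, metric="braycurtis"))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = nb.permanova(dm, labels, n_perm=999)
        assert res.method == "exhaustive"
        assert res.n_permutations == 20
        assert res.pseudo_f == pytest.approx(gower_pseudo_f(dm, labels), rel=1e-9)
        # exhaustive p recomputed by enumerating all 20 assignments
        hits = 0
        for grp in itertools.combinations(range(6), 3):
            perm = np.array(["b"] * 6)
            perm[list(grp)] = "a"
            if gower_pseudo_f(dm, perm) >= res.pseudo_f - 1e-12:
                hits += 1
        assert res.p_value == pytest.approx(hits / 20)

    def test_identical_rows_give_p_one(self):
        dm = np.zeros((4, 4))
        res = nb.permanova(dm, ["a", "a", "b", "b"])
        assert res.p_value == 1.0

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova

        rng = np.random.default_rng(9)
        comp = rng.uniform(0, 1, size=(10, 5))
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(comp, metric="braycurtis"))
        labels = ["a"] * 5 + ["b"] * 5
        ours = nb.permanova(dm, labels, n_perm=99)
        theirs = skbio_permanova(DistanceMatrix(dm), grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_null_p_super_uniform(self):
        """Fraction of p <= 0.05 over 500 exchangeable-null simulations
        stays at or below 0.07."""
        rng = np.random.default_rng(10)
        from scipy.spatial.distance import pdist, squareform

        hits = 0
        n_sim = 500
        labels = ["a"] * 4 + ["b"] * 4
        for _ in range(n_sim):
            comp = rng.uniform(0, 1, size=(8, 4))
            dm = squareform(pdist(comp, metric="braycurtis"))
            if nb.permanova(dm, labels, n_perm=999).p_value <= 0.05:
                hits += 1
        assert hits / n_sim <= 0.07

    def _planted_inputs(self, rng, shift=2.0):
        base = np.array([30, 20, 10, 10, 5.0])
        rows, metas = [], []
        for k in range(24):
            treatment = "water" if k < 12 else "ampicillin"
            mu = base.copy()
            if treatment == "ampicillin":
                mu[3] *= shift
            rows.append(rng.poisson(mu))
            metas.append((f"i{k}", treatment))
        idx = pd.MultiIndex.from_tuples([(i, 0) for i, _ in metas],
                                        names=["image_id", "center_taxon"])
        raw = pd.DataFrame(rows, index=idx, columns=pd.Index(range(5),
                                                             name="neighbor_taxon"))
        abund = pd.DataFrame([base.astype(int)] * 24,
                             index=pd.Index([i for i, _ in metas], name="image_id"))
        meta = make_meta([i for i, _ in metas], day=35)
        meta["treatment"] = [t for _, t in metas]
        return raw, abund, meta

    def test_planted_shift_identifies_driver(self):
        rng = np.random.default_rng(11)
        raw, abund, meta = self._planted_inputs(rng)
        res = nb.neighborhood_permanova(raw, abund, meta, center_taxon=0,
                                        tissue="cecum", day=35,
                                        treatment="ampicillin", n_perm=999, seed=0)
        assert res is not None
        result, coef, top = res
        assert top == 3
        assert result.p_value <= 0.05
        assert coef[3] > 0

    def test_insufficient_groups_return_none(self):
        rng = np.random.default_rng(12)
        raw, abund, meta = self._planted_inputs(rng)
        meta = meta[meta["treatment"] == "water"]
        res = nb.neighborhood_permanova(raw, abund, meta.iloc[:4], center_taxon=0,
                                        tissue="cecum", day=35,
                                        treatment="ampicillin")
        assert res is None


class TestOrdination:
    def test_nmds_equilateral_three_rows(self):
        comp = pd.DataFrame([[1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        coords, stress, _vecs = nb.nmds(comp, seed=0)
        assert stress < 0.01
        d = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None], axis=2)
        side = d[0, 1]
        assert d[0, 2] == pytest.approx(side, rel=0.05)
        assert d[1, 2] == pytest.approx(side, rel=0.05)

    def test_identical_rows_collapse(self):
        comp = pd.DataFrame([[1, 2, 3.0]] * 4)
        coords, stress, _ = nb.nmds(comp, seed=0)
        assert stress == 0.0
        assert np.allclose(coords.to_numpy(), 0.0)

    def test_stress_non_increasing_with_more_iterations(self):
        rng = np.random.default_rng(13)
        comp = pd.DataFrame(rng.uniform(0, 1, size=(12, 6)))
        _, s_short, _ = nb.nmds(comp, seed=0, max_iter=5, n_init=1)
        _, s_long, _ = nb.nmds(comp, seed=0, max_iter=300, n_init=1)
        assert s_long <= s_short + 1e-12

    def test_planted_clusters_separate(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(14)
        a = rng.dirichlet([10, 1, 1, 1], size=10)
        b = rng.dirichlet([1, 1, 10, 10], size=10)
        comp = pd.DataFrame(np.vstack([a, b]))
        coords, _stress, _ = nb.nmds(comp, seed=0)
        labels = [0] * 10 + [1] * 10
        assert silhouette_score(coords.to_numpy(), labels) > 0.5

    def test_umap_deterministic_under_seed(self):
        rng = np.random.default_rng(15)
        comp = pd.DataFrame(rng.uniform(0, 1, size=(20, 5)))
        e1 = nb.ordinate_neighborhoods(comp, method="umap", seed=42)
        e2 = nb.ordinate_neighborhoods(comp, method="umap", seed=42)
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy())

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            nb.ordinate_neighborhoods(pd.DataFrame([[1.0, 2.0]]), method="nmds")
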