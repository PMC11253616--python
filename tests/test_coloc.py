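import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatmicro import coloc

from conftest import make_cells, make_meta


def brute_ordered_pair_counts(xy, taxa, r):
    """O(n^2) oracle: ordered within-radius pair tallies by taxon pair."""
    tally = {}
    n = len(xy)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= r:
                key = (int(taxa[i]), int(taxa[j]))
                tally[key] = tally.get(key, 0) + 1
    return tally


def brute_cs(xy, taxa, r):
    """Independent evaluation of CS = P(AB) / (P(A) P(B)) from the brute scan."""
    tally = brute_ordered_pair_counts(xy, taxa, r)
    total = sum(tally.values())
    n = len(taxa)
    p = {t: (taxa == t).sum() / n for t in set(taxa)}
    out = {}
    for a, b in itertools.combinations_with_replacement(sorted(set(taxa)), 2):
        c = tally.get((a, b), 0)
        out[(a, b)] = np.nan if total == 0 else (c / total) / (p[a] * p[b])
    return out


class TestCountPairs:
    def test_two_cells_within_radius(self):
        cells = make_cells([(0, 0), (4, 0)], [0, 1])
        out = coloc.count_pairs(cells, 5.0)
        got = {(r.taxon_a, r.taxon_b): r.ordered_pair_count for r in out.itertuples()}
        assert got == {(0, 1): 1, (1, 0): 1}

    def test_two_cells_beyond_radius(self):
        cells = make_cells([(0, 0), (6, 0)], [0, 1])
        assert len(coloc.count_pairs(cells, 5.0)) == 0

    def test_single_cell_image_empty(self):
        assert len(coloc.count_pairs(make_cells([(1, 1)], [0]), 5.0)) == 0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            coloc.count_pairs(make_cells([(0, 0)], [0]), 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 120)
        xy = rng.uniform(0, 50, size=(n, 2))
        taxa = rng.integers(0, 4, size=n)
        out = coloc.count_pairs(make_cells(xy, taxa), 5.0)
        got = {(r.taxon_a, r.taxon_b): r.ordered_pair_count for r in out.itertuples()}
        assert got == brute_ordered_pair_counts(xy, taxa, 5.0)


class TestColocScore:
    def test_monospecific_image_scores_one(self):
        cells = make_cells([(0, 0), (1, 0), (2, 0)], [5, 5, 5])
        abund = pd.DataFrame([[3]], index=pd.Index(["img1"], name="image_id"),
                             columns=[5])
        out = coloc.colocalization_score(coloc.count_pairs(cells, 5.0), abund)
        assert out.loc[0, "cs"] == pytest.approx(1.0)

    def test_independence_value(self):
        assert 0.25 / (0.5 * 0.5) == pytest.approx(1.0)  # the normalization target
        # two mixed pairs at independence proportions
        cells = make_cells([(0, 0), (1, 0), (30, 30), (31, 30)], [0, 1, 0, 1])
        abund = pd.DataFrame([[2, 2]], index=pd.Index(["img1"], name="image_id"))
        out = coloc.colocalization_score(coloc.count_pairs(cells, 5.0), abund)
        het = out[(out["taxon_a"] == 0) & (out["taxon_b"] == 1)]
        assert het["p_ab"].iloc[0] == pytest.approx(0.5)
        assert het["cs"].iloc[0] == pytest.approx(0.5 / 0.25)

    def test_ten_cell_fixture_matches_independent_script(self):
        xy = np.array([(1, 1), (2, 1), (3, 4), (8, 2), (9, 3),
                       (20, 20), (21, 21), (22, 20), (40, 5), (41, 6)], float)
        taxa = np.array([0, 1, 0, 2, 2, 1, 1, 0, 2, 0])
        out = coloc.colocalization_score(
            coloc.count_pairs(make_cells(xy, taxa), 5.0),
            pd.DataFrame([[4, 3, 3]], index=pd.Index(["img1"], name="image_id")))
        expected = brute_cs(xy, taxa, 5.0)
        for row in out.itertuples():
            assert row.cs == pytest.approx(expected[(row.taxon_a, row.taxon_b)])

    def test_no_infinities_on_division_guard(self):
        cells = make_cells([(0, 0), (1, 0)], [0, 0])
        abund = pd.DataFrame([[2, 0]], index=pd.Index(["img1"], name="image_id"))
        out = coloc.colocalization_score(coloc.count_pairs(cells, 5.0), abund)
        assert np.isfinite(out["cs"].dropna()).all()


class TestCompareToControl:
    def test_kruskal_hand_rank_calculation(self):
        # ranks 1..6 split cleanly: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7
        h, _p = stats.kruskal([1, 2, 3], [10, 11, 12])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)
        assert coloc.kw_effect_size(h, 2, 6) == pytest.approx((h - 1) / 4)

    def _scores_frame(self, water_vals, treat_vals, pair=(0, 1)):
        rows = []
        ids = []
        for k, v in enumerate(water_vals):
            rows.append((f"w{k}", *pair, v))
            ids.append((f"w{k}", "water"))
        for k, v in enumerate(treat_vals):
            rows.append((f"t{k}", *pair, v))
            ids.append((f"t{k}", "vancomycin"))
        scores = pd.DataFrame(rows, columns=["image_id", "taxon_a", "taxon_b", "cs"])
        meta = make_meta([i for i, _ in ids])
        meta["treatment"] = [t for _, t in ids]
        return scores, meta

    def test_identical_groups_not_significant(self):
        vals = [1.0, 1.2, 0.9, 1.1]
        scores, meta = self._scores_frame(vals, vals)
        out = coloc.compare_to_control(scores, meta)
        assert out.loc[0, "p_adj"] >= 0.05

    def test_separated_groups_flagged_large(self):
        scores, meta = self._scores_frame([1.0, 1.1, 0.9, 1.05, 0.95, 1.0],
                                          [4.0, 4.2, 3.9, 4.1, 4.05, 3.8])
        out = coloc.compare_to_control(scores, meta)
        assert out.loc[0, "p_adj"] < 0.1
        assert out.loc[0, "effsize"] >= 0.14
        assert bool(out.loc[0, "large"])
        assert out.loc[0, "log2fc"] == pytest.approx(np.log2(4.0083333 / 1.0), abs=1e-3)


class TestStratumSummary:
    def test_percent_arithmetic(self):
        assert coloc.percent(42, 1250) == 3.36
        assert coloc.percent(579, 833) == 69.51
        assert coloc.percent(225, 712) == 31.60

    @pytest.mark.parametrize("signif,large,total", [(42, 19, 1250), (0, 0, 7),
                                                    (3, 1, 9)])
    def test_summary_counts_and_percents(self, signif, large, total):
        rows = []
        for k in range(total):
            p_adj = 0.01 if k < signif else 0.5
            rows.append(("cecum", 35, "ampicillin", 0, k + 1, 6, 6, 1.0, p_adj,
                         0.0, False, p_adj, 0.2 if k < large else np.nan, k < large))
        comp = pd.DataFrame(rows, columns=[
            "tissue", "day", "treatment", "taxon_a", "taxon_b", "n_treat",
            "n_control", "h_stat", "p_kw", "log2fc", "fold_change_flag",
            "p_adj", "effsize", "large"])
        out = coloc.summarize_strata(comp)
        assert out.loc[0, "signif"] == signif
        assert out.loc[0, "total_colocs"] == total
        assert out.loc[0, "pct_signif"] == round(100 * signif / total, 2)
        assert out.loc[0, "pct_large_effsize"] == round(100 * large / total, 2)


def _comparison_row(a, b, log2fc, p_adj, tissue="cecum", treatment="ampicillin",
                    day=35, flag=False):
    return dict(tissue=tissue, day=day, treatment=treatment, taxon_a=a, taxon_b=b,
                n_treat=6, n_control=6, h_stat=1.0, p_kw=p_adj, log2fc=log2fc,
                fold_change_flag=flag, p_adj=p_adj, effsize=np.nan, large=False)


class TestHeatmapFilterAndNetwork:
    def _abund(self, totals, n_images=8):
        per = {t: [tot // n_images] * n_images for t, tot in totals.items()}
        return pd.DataFrame(per, index=pd.Index([f"i{k}" for k in range(n_images)],
                                                name="image_id"))

    def test_rare_taxon_pairs_removed(self):
        abund = self._abund({0: 1992, 1: 4000, 2: 4000})  # 1992 < 2000
        comp = pd.DataFrame([_comparison_row(0, 1, 3.0, 0.001),
                             _comparison_row(1, 2, 3.0, 0.001)])
        _f, kept = coloc.heatmap_filter(comp, abund)
        assert (0, 1) not in kept
        assert (1, 2) in kept

    def test_small_log2fc_removed(self):
        abund = self._abund({1: 4000, 2: 4000})
        comp = pd.DataFrame([_comparison_row(1, 2, 0.5, 0.001)])
        _f, kept = coloc.heatmap_filter(comp, abund)
        assert kept == set()

    def test_low_prevalence_removed(self):
        abund = self._abund({1: 4000, 2: 4000})
        abund[2] = [4000] + [0] * 7  # one image out of eight
        comp = pd.DataFrame([_comparison_row(1, 2, 3.0, 0.001)])
        _f, kept = coloc.heatmap_filter(comp, abund)
        assert kept == set()

    def test_flagged_fold_changes_excluded(self):
        abund = self._abund({1: 4000, 2: 4000})
        comp = pd.DataFrame([_comparison_row(1, 2, 900.0, 0.001, flag=True)])
        _f, kept = coloc.heatmap_filter(comp, abund)
        assert kept == set()

    def test_network_single_edge_and_self_removed(self):
        filtered = pd.DataFrame([_comparison_row(0, 1, 2.0, 0.01),
                                 _comparison_row(2, 2, 5.0, 0.01)])
        filtered["pair"] = "x"
        edges = coloc.build_network(filtered, "cecum", "ampicillin", 35)
        assert len(edges) == 1
        assert edges.loc[0, ["taxon_a", "taxon_b"]].tolist() == [0, 1]
        assert edges.loc[0, "weight"] == 2.0
        assert edges.loc[0, "sign"] == 1.0

    def test_edge_count_equals_unique_heterospecific_pairs(self):
        rows = [_comparison_row(a, b, 1.5, 0.01)
                for a, b in [(0, 1), (0, 2), (1, 2), (3, 3)]]
        filtered = pd.DataFrame(rows)
        edges = coloc.build_network(filtered, "cecum", "ampicillin", 35)
        assert len(edges) == 3
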