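import numpy as np
import pandas as pd
import pytest

from lcarisk.adjustment import (
    adjusted_km_curves,
    adjustment_report,
    class_mixture_cif,
    concordance_index,
    rescaled_weights,
    robust_score_test,
)
from lcarisk.survival import aalen_johansen, km_estimator, naive_cif, sup_distance
from lcarisk.synthetic import confounded_subtype_config, default_config, simulate_cohort


def hand_logrank(time, event, group):
    """Textbook two-group log-rank chi-square (hypergeometric variance)."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    g = np.asarray(group)
    o_minus_e, var = 0.0, 0.0
    for tj in np.unique(time[event == 1]):
        at = time >= tj
        n, n1 = at.sum(), (at & (g == "B")).sum()
        d = ((time == tj) & (event == 1)).sum()
        d1 = ((time == tj) & (event == 1) & (g == "B")).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestRescaledWeights:
    def test_hand_two_by_two_table(self):
        """30/10 vs 10/30 split: base weights 2/3 and 2, rescale factor 1."""
        g = np.array(["g1"] * 40 + ["g2"] * 40)
        z = np.array(["z1"] * 30 + ["z2"] * 10 + ["z1"] * 10 + ["z2"] * 30)
        ws = rescaled_weights(g, z)
        np.testing.assert_allclose(ws.weights[:30], 2 / 3)
        np.testing.assert_allclose(ws.weights[30:40], 2.0)
        np.testing.assert_allclose(ws.weights[40:50], 2.0)
        np.testing.assert_allclose(ws.weights[50:], 2 / 3)

    def test_group_sums_and_balance_exact(self):
        rng = np.random.default_rng(0)
        g = rng.choice(["a", "b", "c"], 500)
        z = rng.choice(["1", "2", "3", "4"], 500)
        ws = rescaled_weights(g, z)
        marg = pd.Series(z).value_counts(normalize=True)
        for lv in np.unique(g):
            m = g == lv
            assert ws.weights[m].sum() == pytest.approx(m.sum(), abs=1e-9)
            for cls in np.unique(z):
                share = ws.weights[m & (z == cls)].sum() / m.sum()
                assert share == pytest.approx(marg[cls], abs=1e-9)

    def test_identical_composition_gives_unit_weights(self):
        g = np.array(["g1"] * 20 + ["g2"] * 20)
        z = np.tile(["z1"] * 10 + ["z2"] * 10, 2)
        ws = rescaled_weights(g, z)
        np.testing.assert_allclose(ws.weights, 1.0, atol=1e-12)

    def test_empty_cell_warns(self):
        g = np.array(["g1"] * 4 + ["g2"] * 4)
        z = np.array(["z1", "z1", "z2", "z2", "z1", "z1", "z1", "z1"])
        with pytest.warns(UserWarning, match="empty"):
            ws = rescaled_weights(g, z)
        assert not ws.complete


class TestAdjustedCurves:
    def test_unit_weights_reproduce_unadjusted_bitwise(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200)
        e = rng.integers(0, 2, 200)
        g = rng.choice(["A", "B"], 200)
        res = adjusted_km_curves(t, e, g, np.ones(200))
        for lv in ("A", "B"):
            np.testing.assert_array_equal(res.adjusted[lv].values, res.unadjusted[lv].values)

    def test_identical_composition_leaves_curves_unchanged(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 200)
        e = rng.integers(0, 2, 200)
        g = np.array(["A"] * 100 + ["B"] * 100)
        z = np.tile(["z1"] * 50 + ["z2"] * 50, 2)
        ws = rescaled_weights(g, z)
        res = adjusted_km_curves(t, e, g, ws)
        for lv in ("A", "B"):
            np.testing.assert_allclose(res.adjusted[lv].values, res.unadjusted[lv].values)

    def test_single_group_equals_marginal_km(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        g = np.array(["A"] * 100)
        z = rng.choice(["z1", "z2"], 100)
        ws = rescaled_weights(g, z)
        res = adjusted_km_curves(t, e, g, ws)
        km = km_estimator(t, e)
        np.testing.assert_allclose(res.adjusted["A"].values, km.values, atol=1e-9)


class TestClassMixtureCIF:
    def test_single_class_equals_naive(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 300)
        e = rng.choice([0, 1, 2], 300)
        mix = class_mixture_cif(t, e, 1, np.array(["c1"] * 300))
        nv = naive_cif(t, e, 1)
        np.testing.assert_allclose(mix(mix.times), nv(mix.times), atol=1e-12)

    def test_convex_combination_bounds(self):
        cfg = default_config(n_patients=2000, seed=6)
        co = simulate_cohort(cfg)
        labels = co.data["true_class"].astype(str).to_numpy()
        mix = class_mixture_cif(co.time, co.event, 1, labels)
        strata = [
            naive_cif(co.time[labels == lv], co.event[labels == lv], 1)
            for lv in np.unique(labels)
        ]
        lo = np.min([c(mix.times) for c in strata], axis=0)
        hi = np.max([c(mix.times) for c in strata], axis=0)
        assert (mix.values >= lo - 1e-12).all() and (mix.values <= hi + 1e-12).all()

    def test_class_independent_hazards_match_pooled_naive(self):
        cfg = default_config(n_patients=4000, seed=7)
        cfg.cause_hr = np.ones((4, 2))
        co = simulate_cohort(cfg)
        labels = co.data["true_class"].astype(str).to_numpy()
        mix = class_mixture_cif(co.time, co.event, 1, labels)
        nv = naive_cif(co.time, co.event, 1)
        assert sup_distance(mix, nv) < 0.03  # Monte-Carlo tolerance

    def test_small_strata_pooled_with_warning(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 120)
        e = rng.choice([0, 1, 2], 120)
        labels = np.array(["big"] * 110 + ["tiny"] * 10)
        with pytest.warns(UserWarning, match="pooled"):
            mix = class_mixture_cif(t, e, 1, labels, min_stratum=50)
        nv = naive_cif(t, e, 1)
        np.testing.assert_allclose(mix(mix.times), nv(mix.times), atol=1e-12)

    def test_all_strata_small_falls_back_to_naive(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 40)
        e = rng.choice([0, 1], 40)
        labels = rng.choice(["a", "b"], 40)
        with pytest.warns(UserWarning, match="falling back"):
            mix = class_mixture_cif(t, e, 1, labels, min_stratum=50)
        nv = naive_cif(t, e, 1)
        np.testing.assert_allclose(mix(mix.times), nv(mix.times), atol=1e-12)


class TestRobustScoreTest:
    def test_matches_hand_logrank_on_toy(self):
        """6 patients, no ties: the score chi-square is the log-rank statistic."""
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 1, 0, 1, 0])
        g = np.array(["A", "B", "A", "B", "B", "A"])
        res = robust_score_test(t, e, g)
        assert res.statistic == pytest.approx(hand_logrank(t, e, g), abs=1e-6)
        assert res.df == 1

    def test_null_permutations_rarely_reject(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 120)
        e = rng.integers(0, 2, 120)
        rejections = 0
        for _ in range(30):
            g = rng.permutation(np.array(["A"] * 60 + ["B"] * 60))
            rejections += robust_score_test(t, e, g).p_value < 0.05
        assert rejections <= 5  # expected 1.5 under the null

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(11)
        t = np.concatenate([rng.exponential(2, 100), rng.exponential(20, 100)])
        e = np.ones(200, int)
        g = np.array(["A"] * 100 + ["B"] * 100)
        assert robust_score_test(t, e, g).p_value < 1e-10

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 150)
        e = rng.integers(0, 2, 150)
        g = rng.choice(["A", "B"], 150)
        w = rng.uniform(0.5, 2.0, 150)
        s1 = robust_score_test(t, e, g, weights=w).statistic
        s2 = robust_score_test(t, e, g, weights=17.3 * w).statistic
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            robust_score_test([1, 2], [1, 1], ["A", "A"])


class TestConcordance:
    def test_perfect_ordering(self):
        res = concordance_index([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 2, 1])
        assert res.cindex == 1.0

    def test_constant_score_is_half(self):
        res = concordance_index([1, 2, 3, 4], [1, 1, 1, 1], [2, 2, 2, 2])
        assert res.cindex == 0.5

    def test_hand_enumeration_five_sixths(self):
        res = concordance_index([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 1, 2])
        assert res.n_pairs == 6
        assert res.n_concordant == 5
        assert res.cindex == pytest.approx(5 / 6)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(13)
        t = rng.exponential(10, 300)
        e = rng.integers(0, 2, 300)
        s = rng.normal(size=300)
        ours = concordance_index(t, e, s).cindex
        theirs = ll_cindex(t, -s, e)  # lifelines expects higher = longer survival
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_flagged(self):
        with pytest.warns(UserWarning, match="no comparable"):
            res = concordance_index([1, 2], [0, 0], [1, 2])
        assert np.isnan(res.cindex)


class TestAdjustmentReport:
    def test_no_confounding_leaves_metrics_close(self):
        cfg = confounded_subtype_config(n_patients=1500, seed=20)
        cfg.subtype_given_class = np.full((4, 2), 0.5)  # subtype independent of class
        co = simulate_cohort(cfg)
        rep = adjustment_report(
            co.time, (co.event > 0).astype(int),
            co.data["subtype"].to_numpy(),
            co.data["true_class"].astype(str).to_numpy(),
            include_pairs=False,
        )
        row = rep.iloc[0]
        assert row["cindex_adjusted"] == pytest.approx(row["cindex_unadjusted"], abs=0.02)

    def test_identical_subtypes_near_half_concordance(self):
        rng = np.random.default_rng(21)
        t = np.tile(rng.exponential(10, 200), 2)
        e = np.tile(rng.integers(0, 2, 200), 2)
        sub = np.array(["A"] * 200 + ["B"] * 200)
        cls = np.tile(rng.choice(["1", "2"], 200), 2)
        rep = adjustment_report(t, e, sub, cls, include_pairs=False)
        row = rep.iloc[0]
        assert row["cindex_unadjusted"] == pytest.approx(0.5, abs=0.02)
        assert row["cindex_adjusted"] == pytest.approx(0.5, abs=0.02)

    def test_pairwise_rows_present_for_three_subtypes(self):
        rng = np.random.default_rng(22)
        n = 300
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        sub = rng.choice(["A", "B", "C"], n)
        cls = rng.choice(["1", "2"], n)
        rep = adjustment_report(t, e, sub, cls)
        assert set(rep["comparison"]) == {"all", "A vs B", "A vs C", "B vs C"}
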