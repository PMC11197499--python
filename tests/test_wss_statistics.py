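"""WSS ratios and the statistical battery, cross-checked against oracles."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from hemoshear.vessel_anatomy import (CURVE_SIDE_IDS, QUADRANT_IDS,
                                      WallRegionLabels)
from hemoshear.wall_shear import WSSField
from hemoshear.wss_statistics import (cohen_kappa, fisher_exact, icc,
                                      one_way_anova_posthoc, paired_t,
                                      regional_wss_table, rwss_inner_outer,
                                      rwss_vi_ds, two_sample_t,
                                      two_sample_t_summary)


def _field_and_labels(mags, quadrants, curve_sides=None, areas=None):
    n = len(mags)
    areas = np.ones(n) if areas is None else np.asarray(areas, dtype=float)
    vecs = np.zeros((n, 3))
    vecs[:, 0] = mags
    field = WSSField(np.arange(n), np.zeros((n, 3, 3)),
                     np.tile([0.0, 1.0, 0.0], (n, 1)), vecs,
                     np.asarray(mags, dtype=float), areas, np.zeros((n, 3)))
    if curve_sides is None:
        curve_sides = np.full(n, CURVE_SIDE_IDS["undefined"])
    labels = WallRegionLabels(np.arange(n), np.zeros(n, dtype=int),
                              np.asarray(quadrants), np.asarray(curve_sides))
    return field, labels


class TestRatios:
    def test_uniform_field_gives_unity(self):
        f, l = _field_and_labels([5.0] * 8, [0, 1, 2, 3] * 2)
        assert rwss_vi_ds(f, l) == pytest.approx(1.0)

    def test_group_means_ratio(self):
        # ventral+inferior faces at 6.41 Pa, dorsal+superior at 8.91 Pa:
        # the ratio of the mid-segment group means
        q = [QUADRANT_IDS["ventral"], QUADRANT_IDS["inferior"],
             QUADRANT_IDS["dorsal"], QUADRANT_IDS["superior"]]
        f, l = _field_and_labels([6.41, 6.41, 8.91, 8.91], q)
        assert rwss_vi_ds(f, l) == pytest.approx(6.41 / 8.91, rel=1e-9)
        assert rwss_vi_ds(f, l) == pytest.approx(0.719, abs=5e-4)

    def test_scale_invariance(self):
        q = [0, 3, 1, 2]
        f1, l = _field_and_labels([2.0, 4.0, 5.0, 7.0], q)
        f2, _ = _field_and_labels([20.0, 40.0, 50.0, 70.0], q)
        assert rwss_vi_ds(f1, l) == pytest.approx(rwss_vi_ds(f2, l), rel=1e-12)

    def test_inner_outer_ratio(self):
        sides = [CURVE_SIDE_IDS["inner"], CURVE_SIDE_IDS["inner"],
                 CURVE_SIDE_IDS["outer"], CURVE_SIDE_IDS["outer"]]
        f, l = _field_and_labels([6.31, 6.31, 8.24, 8.24], [0, 1, 2, 3], sides)
        assert rwss_inner_outer(f, l) == pytest.approx(6.31 / 8.24, rel=1e-9)
        assert rwss_inner_outer(f, l) == pytest.approx(0.766, abs=5e-4)

    def test_straight_vessel_has_no_curve_sides(self):
        f, l = _field_and_labels([1.0, 2.0], [0, 1])
        with pytest.raises(ValueError, match="undefined"):
            rwss_inner_outer(f, l)

    def test_empty_group_rejected(self):
        f, l = _field_and_labels([1.0, 2.0], [QUADRANT_IDS["ventral"]] * 2)
        with pytest.raises(ValueError, match="empty"):
            rwss_vi_ds(f, l)

    def test_regional_table_shape(self):
        f, l = _field_and_labels([1.0, 2.0, 3.0, 4.0], [0, 1, 2, 3])
        df = regional_wss_table(f, l)
        assert set(df.columns) == {"vessel_id", "segment", "region",
                                   "mean_wss_pa", "total_area_m2", "n_faces"}
        assert len(df) == 4  # one proximal row per quadrant, no curve sides


class TestPairedT:
    def test_constant_shift_is_overwhelming(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 5)
        res = paired_t(a, a + 2.0 + rng.normal(0, 1e-4, 5))
        assert res.p_value < 1e-6

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        assert paired_t(a, b).statistic == pytest.approx(-paired_t(b, a).statistic)

    def test_matches_textbook_formula(self):
        a = np.array([5.1, 4.8, 6.0, 5.5, 5.9])
        b = np.array([4.9, 4.9, 5.2, 5.4, 5.1])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert paired_t(a, b).statistic == pytest.approx(t_hand)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestTwoSampleT:
    def test_identical_summaries(self):
        res = two_sample_t_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_swap_antisymmetry(self):
        r1 = two_sample_t_summary(5.0, 1.0, 12, 6.0, 2.0, 20)
        r2 = two_sample_t_summary(6.0, 2.0, 20, 5.0, 1.0, 12)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_raw_and_summary_agree(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1.5, 25)
        r1 = two_sample_t(a, b)
        r2 = two_sample_t_summary(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b))
        assert r1.statistic == pytest.approx(r2.statistic)


class TestAnova:
    def test_identical_groups(self):
        g = [np.array([1.0, 2, 3, 4])] * 4
        res = one_way_anova_posthoc(g)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert all(p == 1.0 for p in res.pairwise_p.values())

    def test_bonferroni_is_six_times_raw_for_four_groups(self):
        rng = np.random.default_rng(5)
        g = [rng.normal(m, 1, 12) for m in (0.0, 0.3, 0.6, 0.9)]
        from scipy import stats as ss

        res = one_way_anova_posthoc(g)
        for (i, j), p in res.pairwise_p.items():
            raw = ss.ttest_ind(g[i], g[j], equal_var=True).pvalue
            assert p == pytest.approx(min(1.0, 6 * raw))

    def test_omnibus_matches_hand_sum_of_squares(self):
        rng = np.random.default_rng(6)
        g = [rng.normal(m, 1.2, n) for m, n in ((0, 8), (1, 10), (0.5, 9), (2, 7))]
        allv = np.concatenate(g)
        grand = allv.mean()
        ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in g)
        ss_within = sum(((x - x.mean()) ** 2).sum() for x in g)
        df_b, df_w = len(g) - 1, len(allv) - len(g)
        f_hand = (ss_between / df_b) / (ss_within / df_w)
        assert one_way_anova_posthoc(g).f_statistic == pytest.approx(f_hand)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova_posthoc([[1.0], [2.0, 3.0]])


def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = rng.integers(0, 16, size=(2, 2))
            assert fisher_exact(t) == pytest.approx(fisher_oracle(t), abs=1e-10)

    def test_empty_margins_are_certain(self):
        assert fisher_exact([[0, 0], [3, 4]]) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestAgreement:
    def test_identical_ratings_kappa_one(self):
        a = np.array([0, 1, 2, 1, 0, 2, 2])
        res = cohen_kappa(a, a)
        assert res.value == pytest.approx(1.0)
        assert res.excellent

    def test_independent_ratings_kappa_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 4, 10_000)
        b = rng.integers(0, 4, 10_000)
        assert abs(cohen_kappa(a, b).value) < 0.03

    def test_kappa_matches_hand_formula(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 3, 60)
        b = np.where(rng.random(60) < 0.7, a, rng.integers(0, 3, 60))
        p_o = np.mean(a == b)
        p_e = sum(np.mean(a == k) * np.mean(b == k) for k in range(3))
        assert cohen_kappa(a, b).value == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_threshold_is_strictly_above_075(self):
        # 0.751 counts as excellent, 0.75 itself does not
        from hemoshear.wss_statistics import EXCELLENT_AGREEMENT

        assert 0.751 > EXCELLENT_AGREEMENT
        assert not (0.75 > EXCELLENT_AGREEMENT)

    def test_single_category_undefined(self):
        res = cohen_kappa(np.zeros(10, dtype=int), np.zeros(10, dtype=int))
        assert not res.defined and np.isnan(res.value)

    def test_icc_identical_columns(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 40)
        res = icc(np.column_stack([a, a, a]))
        assert res.value == pytest.approx(1.0)
        assert res.excellent and res.model == "ICC2"

    def test_icc_overwhelming_noise_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 200)
        res = icc(np.column_stack([a, a + rng.normal(0, 6, 200)]))
        assert abs(res.value) < 0.15

    def test_icc_recovers_constructed_ground_truth(self):
        # variance components chosen for ICC2 = 0.8: σs²=0.8, σr²=0.05, σe²=0.15
        rng = np.random.default_rng(12)
        n, k = 500, 3
        m = (rng.normal(0, np.sqrt(0.8), n)[:, None]
             + rng.normal(0, np.sqrt(0.05), k)[None, :]
             + rng.normal(0, np.sqrt(0.15), (n, k)))
        assert icc(m).value == pytest.approx(0.8, abs=0.05)

    def test_icc_no_between_subject_variance_undefined(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        res = icc(m)
        assert not res.defined


class TestPValueRanges:
    def test_all_p_values_in_unit_interval(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a, b = rng.normal(0, 1, 8), rng.normal(0, 2, 8)
            assert 0.0 <= paired_t(a, b).p_value <= 1.0
            assert 0.0 <= two_sample_t(a, b).p_value <= 1.0
            t = rng.integers(0, 20, (2, 2))
            assert 0.0 <= fisher_exact(t) <= 1.0
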