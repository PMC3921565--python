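"""Unit and property tests for the shared statistical engine.

Frozen expected values for the ANOVAs come from independent oracles: R's
``car::Anova(type=3)`` for the unbalanced two-way design and R ``aov`` with
``Error(subject/time)`` strata for the mixed design; the small-sample BH and
binomial cases are evaluated by hand / explicit summation in the tests.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from agestress import stats_core as sc


class TestTwoWayAnova:
    def test_unbalanced_type3_matches_r_oracle(self):
        # cells: A1B1 (1,2,3) A1B2 (4,5) A2B1 (6,7) A2B2 (8,9,10,12)
        y = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12]
        a = ["A1"] * 5 + ["A2"] * 6
        b = ["B1", "B1", "B1", "B2", "B2", "B1", "B1", "B2", "B2", "B2", "B2"]
        res = sc.two_way_anova(y, a, b)
        assert res["A"].f == pytest.approx(35.76820, abs=1e-4)
        assert res["A"].p == pytest.approx(0.00055283, abs=1e-7)
        assert res["B"].f == pytest.approx(12.44009, abs=1e-4)
        assert res["B"].p == pytest.approx(0.00963591, abs=1e-7)
        assert res["A:B"].f == pytest.approx(0.21165, abs=1e-4)
        assert res["A:B"].p == pytest.approx(0.65942877, abs=1e-6)
        assert res["A"].df_num == 1 and res["A"].df_den == 7
        assert res.mse_within == pytest.approx(11.75 / 7)

    def test_balanced_toy_matches_hand_sums_of_squares(self):
        # {A1B1:(1,2), A1B2:(3,4), A2B1:(5,6), A2B2:(7,8)}; by hand:
        # SS_A = 32 (F=64), SS_B = 8 (F=16), SS_AB = 0, MSE = 0.5, df_err = 4
        y = [1, 2, 3, 4, 5, 6, 7, 8]
        a = ["A1"] * 4 + ["A2"] * 4
        b = ["B1", "B1", "B2", "B2"] * 2
        res = sc.two_way_anova(y, a, b)
        assert res["A"].f == pytest.approx(64.0)
        assert res["A"].p == pytest.approx(sps.f.sf(64.0, 1, 4))
        assert res["B"].f == pytest.approx(16.0)
        assert res["A:B"].f == pytest.approx(0.0, abs=1e-10)

    def test_equal_cell_means_give_null_result(self, rng):
        spread = np.array([-1.0, 0.0, 1.0])
        y = np.concatenate([5.0 + spread] * 4)
        a = np.repeat(["A1", "A2"], 6)
        b = np.tile(np.repeat(["B1", "B2"], 3), 2)
        res = sc.two_way_anova(y, a, b)
        for fac in res.factors:
            assert fac.f == pytest.approx(0.0, abs=1e-10)
            assert fac.p == pytest.approx(1.0)

    def test_relabeling_invariance(self, rng):
        y = rng.normal(size=16)
        a = np.repeat(["A1", "A2"], 8)
        b = np.tile(np.repeat(["B1", "B2"], 4), 2)
        res1 = sc.two_way_anova(y, a, b)
        swap = {"A1": "A2", "A2": "A1"}
        res2 = sc.two_way_anova(y, [swap[x] for x in a], b)
        for f1, f2 in zip(res1.factors, res2.factors):
            assert f1.f == pytest.approx(f2.f)
            assert f1.p == pytest.approx(f2.p)

    def test_design_errors(self):
        with pytest.raises(ValueError, match="empty|n < 2"):
            sc.two_way_anova([1, 2, 3, 4, 5, 6],
                             ["A1", "A1", "A1", "A1", "A2", "A2"],
                             ["B1", "B1", "B2", "B2", "B1", "B1"])
        with pytest.raises(ValueError, match="levels"):
            sc.two_way_anova([1, 2, 3, 4], ["A"] * 4, ["B1", "B1", "B2", "B2"])

    def test_zero_within_cell_variance_flagged(self):
        y = [1, 1, 2, 2, 3, 3, 4, 4]
        a = ["A1"] * 4 + ["A2"] * 4
        b = ["B1", "B1", "B2", "B2"] * 2
        res = sc.two_way_anova(y, a, b)
        assert res.degenerate
        assert res["A"].p == 0.0      # real between-group differences
        assert res["A:B"].p == 1.0    # no interaction pattern

    def test_planted_age_effect_detected_under_noise(self):
        # large age shift, no stress effect: age significant, stress not,
        # in >= 95% of seeded replicates
        a = np.repeat(["young", "aged"], 20)
        b = np.tile(np.repeat(["c", "s"], 10), 2)
        hits_age = hits_stress = 0
        n = 200
        rng = np.random.default_rng(42)
        for _ in range(n):
            y = rng.normal(size=40) + np.where(a == "aged", 3.0, 0.0)
            res = sc.two_way_anova(y, a, b, names=("age", "stress"))
            hits_age += res["age"].p < 0.05
            hits_stress += res["stress"].p > 0.05
        assert hits_age / n >= 0.95
        assert hits_stress / n >= 0.95

    def test_matrix_engine_agrees_with_scalar_engine(self, rng):
        a = np.array(["y"] * 18 + ["o"] * 19, dtype=object)
        b = np.array(["c"] * 10 + ["s"] * 8 + ["c"] * 10 + ["s"] * 9,
                     dtype=object)
        y = rng.normal(size=(12, 37))
        mat = sc.two_way_anova_matrix(y, a, b, names=("age", "stress"))
        for i in range(len(y)):
            res = sc.two_way_anova(y[i], a, b, names=("age", "stress"))
            for name in ("age", "stress", "age:stress"):
                assert mat[f"p_{name}"][i] == pytest.approx(res[name].p,
                                                            abs=1e-10)
                assert mat[f"F_{name}"][i] == pytest.approx(res[name].f,
                                                            rel=1e-8)


class TestMixedAnova:
    def test_matches_r_aov_error_strata_oracle(self):
        y = np.array([[3, 5, 4], [4, 6, 5], [2, 5, 6],
                      [7, 9, 12], [8, 10, 11]], dtype=float)
        g = ["g1", "g1", "g1", "g2", "g2"]
        res = sc.two_way_rm_anova(y, g)
        assert res["group"].f == pytest.approx(160.27742, abs=1e-4)
        assert res["group"].p == pytest.approx(0.0010629, abs=1e-6)
        assert (res["group"].df_num, res["group"].df_den) == (1, 3)
        assert res["time"].f == pytest.approx(14.67, abs=1e-3)
        assert res["time"].p == pytest.approx(0.0048939, abs=1e-6)
        assert (res["time"].df_num, res["time"].df_den) == (2, 6)
        assert res["group:time"].f == pytest.approx(2.58, abs=1e-3)
        assert res["group:time"].p == pytest.approx(0.1554036, abs=1e-6)
        assert res.mse_within == pytest.approx(0.57407407, abs=1e-7)

    def test_identical_trajectories_null_between_effect(self):
        traj = np.array([1.0, 2.0, 3.0])
        y = np.tile(traj, (6, 1))
        res = sc.two_way_rm_anova(y, ["a"] * 3 + ["b"] * 3)
        assert res["group"].f == pytest.approx(0.0, abs=1e-10)
        assert res["group"].p == pytest.approx(1.0)

    def test_rejects_missing_or_single_timepoint(self):
        y = np.ones((4, 3))
        y[0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sc.two_way_rm_anova(y, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="repeated"):
            sc.two_way_rm_anova(np.ones((4, 1)), ["a", "a", "b", "b"])

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        n = 100
        g = np.repeat(["improves", "flat"], 8)
        for _ in range(n):
            y = rng.normal(size=(16, 4))
            y[:8] += np.arange(4) * 2.0      # one group improves over time
            res = sc.two_way_rm_anova(y, g)
            hits += res["group:time"].p < 0.05
        assert hits / n >= 0.95


class TestFishersLsd:
    def test_hand_formula_and_cdf_oracle(self):
        cells = {"a": [9, 10, 11, 10], "b": [7, 8, 9, 8]}
        pw = sc.fishers_lsd(cells, mse_within=4.0, df_error=12, pair=("a", "b"))
        assert pw.t == pytest.approx(2.0 / math.sqrt(4.0 * 0.5))
        assert pw.p == pytest.approx(2 * sps.t.sf(abs(pw.t), 12))

    def test_identical_means(self):
        cells = {"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]}
        pw = sc.fishers_lsd(cells, 1.0, 4, ("a", "b"))
        assert pw.t == 0.0 and pw.p == 1.0

    def test_pair_swap_antisymmetry(self):
        cells = {"a": [10.0, 11.0], "b": [8.0, 9.0]}
        p1 = sc.fishers_lsd(cells, 2.0, 6, ("a", "b"))
        p2 = sc.fishers_lsd(cells, 2.0, 6, ("b", "a"))
        assert p1.mean_diff == -p2.mean_diff
        assert p1.p == pytest.approx(p2.p)


class TestStudentsT:
    def test_hand_formula(self):
        a = np.array([4.0, 5.0, 6.0, 7.0])
        b = np.array([2.0, 3.0, 4.0])
        res = sc.students_t(a, b)
        sp2 = (3 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 5
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 3))
        assert res.t == pytest.approx(t_hand)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), 5))

    def test_identical_samples(self):
        res = sc.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_null_struggle_counts_rarely_significant(self):
        # both groups drawn from the same distribution around 29.6 struggles
        rng = np.random.default_rng(17)
        n = 200
        nonsig = sum(
            sc.students_t(rng.normal(29.6, 24.0, 10),
                          rng.normal(29.6, 24.0, 10)).p > 0.05
            for _ in range(n))
        assert nonsig / n >= 0.90


class TestFdr:
    def test_step_up_rule_by_hand(self):
        # thresholds (i/4)*0.05 = .0125, .025, .0375, .05; p_(4)=.04 <= .05
        # so the largest satisfying rank is 4: everything is rejected
        res = sc.fdr_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert res.rejected.all()
        # BH adjusted: p_i * m / i with monotone enforcement = 0.04 each
        assert np.allclose(res.adjusted, 0.04)

    def test_all_ones_and_single_small(self):
        assert not sc.fdr_correct([1.0, 1.0, 1.0]).rejected.any()
        assert sc.fdr_correct([0.04], q=0.05).rejected.all()
        assert sc.fdr_correct([], q=0.05).rejected.size == 0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_rejections_nest_across_q_and_adjusted_monotone(self, ps):
        lo = sc.fdr_correct(ps, q=0.01)
        hi = sc.fdr_correct(ps, q=0.10)
        assert set(np.flatnonzero(lo.rejected)) <= set(np.flatnonzero(hi.rejected))
        order = np.argsort(ps)
        adj = sc.fdr_correct(ps, q=0.05).adjusted[order]
        assert (np.diff(adj) >= -1e-12).all()


class TestBinomialAgreement:
    def test_small_exact_values(self):
        assert sc.binomial_agreement_test(2, 2, 0.5) == pytest.approx(0.25)
        assert sc.binomial_agreement_test(0, 7, 0.5) == pytest.approx(1.0)

    def test_explicit_summation_oracle_45_of_56(self):
        p_oracle = sum(math.comb(56, k) for k in range(45, 57)) / 2 ** 56
        p = sc.binomial_agreement_test(45, 56, 0.5)
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert p < 0.001

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sc.binomial_agreement_test(1, 0)
        with pytest.raises(ValueError):
            sc.binomial_agreement_test(5, 3)


class TestEffectSize:
    def test_simple_two_sd_case(self):
        stress = [9.0, 10.0, 11.0]
        control = [7.0, 8.0, 9.0]
        es = sc.effect_size(stress, control)
        assert es.value == pytest.approx(2.0)

    def test_identical_groups_raise_or_zero(self):
        es = sc.effect_size([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert es.value == pytest.approx(0.0)
        with pytest.raises(ValueError, match="pooled"):
            sc.effect_size([1.0, 1.0], [1.0, 1.0])

    def test_unequal_n_pooled_sd_hand_oracle(self):
        s = np.array([10.0, 12.0, 14.0, 16.0])
        c = np.array([8.0, 9.0, 10.0])
        es = sc.effect_size(s, c)
        sp = math.sqrt((3 * s.var(ddof=1) + 2 * c.var(ddof=1)) / 5)
        assert es.pooled_sd == pytest.approx(sp)
        assert es.value == pytest.approx((s.mean() - c.mean()) / sp)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_antisymmetric_under_group_swap(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=6), r.normal(size=5) + 1.0
        assert sc.effect_size(a, b).value == pytest.approx(
            -sc.effect_size(b, a).value)


def test_expected_null_count_rounds_half_up():
    assert sc.expected_null_count(171, 0.05) == 9
    assert sc.expected_null_count(100, 0.05) == 5
    assert sc.expected_null_count(10, 0.05) == 1  # 0.5 rounds up
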