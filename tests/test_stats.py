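"""Statistics engine: descriptives, normality gate, omnibus tests and
post hoc procedures, each against an independent oracle."""

import math
from itertools import permutations

import numpy as np
import pytest
from scipy import stats as sps

import ferrodial as fd
from ferrodial._round import round_half_up
from ferrodial.stats import TestChoice as Choice, levene

# frozen 9-point standard-normal draw and its Shapiro-Wilk statistic from
# an independent reference implementation (R 4.3 shapiro.test)
NORMAL9 = [0.304717, -1.039984, 0.750451, 0.940565, -1.951035, -1.30218,
           0.12784, -0.316243, -0.016801]
NORMAL9_W = 0.9494499547
NORMAL9_P = 0.6840232623


class TestDescriptive:
    def test_reference_replicates(self):
        s = fd.descriptive([20.1, 22.4, 23.9, 19.8, 22.5, 21.9])
        assert round_half_up(s.mean, 1) == 21.8
        assert round_half_up(s.sd) == 1.56

    def test_constant_sample(self):
        s = fd.descriptive([5.0, 5.0, 5.0])
        assert s.mean == s.median == 5.0
        assert s.sd == 0.0 and s.iqr == 0.0

    def test_linear_interpolation_quantiles(self):
        s = fd.descriptive([1.0, 2.0, 3.0, 4.0])
        assert s.median == pytest.approx(2.5)
        assert s.iqr == pytest.approx(1.5)

    def test_order_statistics(self):
        s = fd.descriptive([3.0, 1.0, 2.0])
        assert s.minimum == 1.0 and s.maximum == 3.0
        assert s.minimum <= s.median <= s.maximum

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fd.descriptive([])


class TestShapiroWilk:
    def test_matches_reference_implementation(self):
        w, p = fd.shapiro_wilk(NORMAL9)
        assert w == pytest.approx(NORMAL9_W, abs=1e-6)
        assert p == pytest.approx(NORMAL9_P, abs=1e-6)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            fd.shapiro_wilk([1.0, 1.0, 1.0])

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            fd.shapiro_wilk([1.0, 2.0])


class TestOneWayAnova:
    def test_hand_computed_f(self):
        # SSB = 6, SSW = 6, df = (2, 6) -> F = 3.0
        f, p = fd.one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)
        assert p == pytest.approx(sps.f.sf(3.0, 2, 6))

    def test_equal_means_give_zero_f(self):
        f, _ = fd.one_way_anova([[1, 3], [0, 4], [2, 2]])
        assert f == pytest.approx(0.0)

    def test_two_groups_equals_squared_t(self):
        a, b = [1.0, 2.5, 3.1, 4.0], [2.0, 3.5, 5.0]
        f, p_f = fd.one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-12)
        assert p_f == pytest.approx(p_t, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fd.one_way_anova([[1.0], [2.0, 3.0]])


class TestTukey:
    FIXTURE = [[1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 4.5, 6.0],
               [2.0, 2.5, 3.5, 3.0]]

    def test_identical_groups_not_significant(self):
        pw = fd.tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pw[0].p == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_reference(self):
        """Cross-check against statsmodels' Tukey HSD."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        values = np.concatenate(self.FIXTURE)
        labels = np.repeat([0, 1, 2], [len(g) for g in self.FIXTURE])
        ref = pairwise_tukeyhsd(values, labels)
        ours = fd.tukey_hsd(self.FIXTURE)
        for comp, p_ref in zip(ours, ref.pvalues):
            assert comp.p == pytest.approx(p_ref, abs=1e-4)

    def test_symmetric_under_relabeling(self):
        pw1 = {frozenset((c.group_a, c.group_b)): c.p
               for c in fd.tukey_hsd(self.FIXTURE, labels=["a", "b", "c"])}
        rev = self.FIXTURE[::-1]
        pw2 = {frozenset((c.group_a, c.group_b)): c.p
               for c in fd.tukey_hsd(rev, labels=["c", "b", "a"])}
        for key in pw1:
            assert pw1[key] == pytest.approx(pw2[key], rel=1e-9)


class TestKruskalWallis:
    def test_hand_rank_arithmetic(self):
        # ranks 1..4, R1 = 3, R2 = 7 -> H = 0.6 * 29 - 15 = 2.4
        h, _ = fd.kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)

    def test_matches_scipy(self):
        groups = [[1.2, 3.4, 2.2], [4.5, 2.1, 6.6], [0.1, 0.5, 0.9, 1.1]]
        h, p = fd.kruskal_wallis(groups)
        h_ref, p_ref = sps.kruskal(*groups)
        assert h == pytest.approx(h_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_within_group_permutation_invariance(self):
        h1, _ = fd.kruskal_wallis([[1, 5, 3], [2, 8, 4]])
        h2, _ = fd.kruskal_wallis([[3, 1, 5], [8, 4, 2]])
        assert h1 == pytest.approx(h2)

    def test_exact_p_matches_label_permutation_oracle(self):
        """Exact mode agrees with brute force over all 4!/(2!2!) distinct
        assignments of ranks to two groups of two."""
        groups = [[1.0, 2.0], [3.0, 4.0]]
        h_obs, p_exact = fd.kruskal_wallis(groups, p_method="exact")
        pooled = [1.0, 2.0, 3.0, 4.0]
        hs = []
        for perm in set(permutations(pooled)):
            hs.append(sps.kruskal(list(perm[:2]), list(perm[2:]))[0])
        oracle = np.mean([h >= h_obs - 1e-12 for h in hs])
        assert p_exact == pytest.approx(oracle)
        assert p_exact == pytest.approx(1 / 3)

    def test_asymptotic_near_exact_on_moderate_sample(self):
        groups = [[1, 5, 7, 11], [2, 3, 8, 12], [4, 6, 9, 10]]
        _, p_asym = fd.kruskal_wallis(groups)
        _, p_exact = fd.kruskal_wallis(groups, p_method="exact")
        assert p_asym == pytest.approx(p_exact, abs=0.05)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            fd.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])


class TestDunn:
    def test_identical_groups_adjusted_p_is_one(self):
        pw = fd.dunn_test([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pw[0].p == pytest.approx(1.0)

    def test_no_tie_fixture_hand_arithmetic(self):
        """Ranks 1..9 in three groups: mean ranks 2, 5, 8; S2 = 7.5;
        z = 3 / sqrt(7.5 * 2/3) = 1.3416408."""
        pw = fd.dunn_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                          adjust="none")
        z = 3.0 / math.sqrt(7.5 * (2 / 3))
        expected = 2 * sps.norm.sf(z)
        assert pw[0].p == pytest.approx(expected, abs=1e-9)
        assert pw[0].p == pytest.approx(0.17971249, abs=1e-6)
        bonf = fd.dunn_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert bonf[0].p == pytest.approx(3 * expected, abs=1e-9)

    def test_tie_correction_hand_arithmetic(self):
        """With ties, S2 = N(N+1)/12 - sum(t^3-t)/(12(N-1)); recomputed
        here from scratch for a fixture with two tie groups."""
        groups = [[1.0, 1.0, 2.0], [2.0, 3.0, 3.0], [4.0, 4.0, 5.0]]
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        mean_ranks = [ranks[i * 3:(i + 1) * 3].mean() for i in range(3)]
        _, counts = np.unique(pooled, return_counts=True)
        s2 = 9 * 10 / 12 - ((counts ** 3 - counts).sum()) / (12 * 8)
        z = (mean_ranks[0] - mean_ranks[2]) / math.sqrt(s2 * (2 / 3))
        expected = min(1.0, 3 * 2 * sps.norm.sf(abs(z)))
        pw = {frozenset((c.group_a, c.group_b)): c.p
              for c in fd.dunn_test(groups, labels=[0, 1, 2])}
        assert pw[frozenset((0, 2))] == pytest.approx(expected, abs=1e-12)

    def test_unadjusted_never_exceeds_adjusted(self):
        groups = [[1, 4, 2], [3, 8, 5], [9, 2, 7], [1, 1, 6]]
        raw = fd.dunn_test(groups, adjust="none")
        bonf = fd.dunn_test(groups, adjust="bonferroni")
        holm = fd.dunn_test(groups, adjust="holm")
        for r, b, h in zip(raw, bonf, holm):
            assert r.p <= b.p + 1e-12
            assert r.p <= h.p + 1e-12
            assert h.p <= b.p + 1e-12

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            fd.dunn_test([[1.0, 1.0], [1.0, 1.0]])


class TestTiers:
    @pytest.mark.parametrize("p,tier", [
        (0.0004, "p<0.001"), (0.004, "p<0.01"), (0.04, "p<0.05"),
        (0.05, "ns"), (0.4, "ns"),
    ])
    def test_threshold_mapping(self, p, tier):
        assert fd.significance_tier(p) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fd.significance_tier(1.5)


class TestCompareGroups:
    def test_normal_groups_take_parametric_branch(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1.0, 9) for loc in (0.0, 0.5, 3.0)]
        res = fd.compare_groups(groups)
        assert res.test_used is Choice.ANOVA_TUKEY
        assert all(p >= 0.05 for p in res.shapiro_p)

    def test_skewed_group_takes_rank_branch(self):
        rng = np.random.default_rng(1)
        skew_rng = np.random.default_rng(0)
        groups = [rng.normal(0.0, 1.0, 9),
                  np.exp(skew_rng.normal(0.0, 2.0, 9)),  # heavy right skew
                  rng.normal(1.0, 1.0, 9)]
        res = fd.compare_groups(groups)
        assert res.test_used is Choice.KRUSKAL_DUNN
        assert min(res.shapiro_p) < 0.05

    def test_constant_group_routes_to_rank_branch(self):
        groups = [[2.0, 2.0, 2.0], [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]]
        res = fd.compare_groups(groups)
        assert res.test_used is Choice.KRUSKAL_DUNN

    def test_pairwise_carry_labels_and_tiers(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 9), rng.normal(10, 1, 9)]
        with pytest.raises(ValueError):
            fd.compare_groups([[1.0, 2.0]])  # fewer than 2 groups
        res = fd.compare_groups(groups, labels=["a", "b"])
        assert {res.pairwise[0].group_a, res.pairwise[0].group_b} == \
            {"a", "b"}
        assert res.pairwise[0].tier == "p<0.001"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            fd.compare_groups([[1.0, 2.0], [3.0, 4.0, 5.0]])


def test_levene_diagnostic_runs():
    stat, p = levene([[1, 2, 3, 4], [2, 4, 6, 8]])
    assert stat >= 0 and 0 <= p <= 1
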