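import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mafitkit.groupstats import (
    adjust_pvalues,
    bonferroni_cutoff,
    classify_lines,
    count_calls,
    kruskal_wallis_blocks,
    rank_levene,
    screen_outliers,
    wilcoxon_rank_sum,
)

from .conftest import make_table


def brute_force_ranksum_p(a, b):
    """Independent oracle: enumerate every split of the pooled midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    mu = n_a * (len(pooled) + 1) / 2
    dev_obs = abs(ranks[:n_a].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        r = wilcoxon_rank_sum([1.0, 2, 3], [1.0, 2, 3])
        assert r.p_value == 1.0

    def test_fully_separated_small_groups(self):
        # all 20 splits of {1,2,3 | 10,11,12}: only the two extremes are as deviant
        r = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert r.p_value == pytest.approx(0.1)

    def test_degenerate_constant_data(self):
        r = wilcoxon_rank_sum([5.0, 5.0], [5.0, 5.0, 5.0])
        assert r.p_value == 1.0
        assert r.degenerate

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=rng.integers(3, 6)).astype(float)
        b = rng.integers(0, 5, size=rng.integers(3, 6)).astype(float)
        r = wilcoxon_rank_sum(a, b)
        assert r.p_value == pytest.approx(brute_force_ranksum_p(a, b))

    def test_large_samples_use_tie_corrected_normal(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        r = wilcoxon_rank_sum(a, b)
        expect = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert r.p_value == pytest.approx(expect)

    def test_type_one_error_calibrated(self, rng):
        n_reject = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, 12)
            if wilcoxon_rank_sum(x[:6], x[6:]).p_value < 0.05:
                n_reject += 1
        # binomial 3 SE tolerance around alpha (exact test is conservative)
        assert n_reject / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)


class TestRankLevene:
    def test_equal_constant_groups_degenerate(self):
        r = rank_levene([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert r.p_value == 1.0
        assert r.degenerate

    def test_detects_tenfold_spread(self, rng):
        hits = 0
        for _ in range(30):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 10, 50)
            if rank_levene([a, b]).p_value < 0.05:
                hits += 1
        assert hits >= 27  # >= 90% power

    def test_three_group_signature(self, rng):
        anc = rng.normal(1, 0.03, 16)
        ctrl = rng.normal(1, 0.05, 10)
        ma = rng.normal(0.9, 0.2, 90)
        r = rank_levene({"ancestor": anc, "control": ctrl, "MA": ma})
        assert r.p_value < 0.05
        assert r.groups == ("MA", "ancestor", "control")

    def test_type_one_error_calibrated(self, rng):
        n_reject = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, 30)
            if rank_levene([x[:15], x[15:]]).p_value < 0.05:
                n_reject += 1
        assert n_reject / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_constant_group_among_varying_not_an_error(self):
        r = rank_levene([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        assert 0 <= r.p_value <= 1


class TestKruskalWallis:
    def test_identical_blocks_statistic_near_zero(self):
        r = kruskal_wallis_blocks({1: [1, 2, 3, 4], 2: [1, 2, 3, 4]})
        assert r.statistic < 0.5
        assert r.p_value > 0.5

    def test_df_is_blocks_minus_one(self, rng):
        r = kruskal_wallis_blocks({b: list(rng.normal(0, 1, 8)) for b in (1, 2, 3)})
        assert r.df == 2

    def test_shifted_blocks_detected(self, rng):
        hits = 0
        for _ in range(40):
            r = kruskal_wallis_blocks({1: rng.normal(0, 1, 8),
                                       2: rng.normal(3, 1, 8)})
            if r.p_value < 0.05:
                hits += 1
        assert hits >= 38  # >= 95% power at a 3 SD shift

    def test_single_block_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis_blocks({1: [1, 2, 3]})


class TestScreenOutliers:
    def test_constant_vector_nothing_flagged(self):
        _, flags = screen_outliers([5.0] * 6)
        assert not flags.any()

    def test_hand_z_score_threshold(self):
        vals = [10.0] * 9 + [0.0]
        # z of the 0 is about 3 (its own presence inflates the SD)
        _, flags4 = screen_outliers(vals, k=4)
        assert not flags4.any()
        _, flags25 = screen_outliers(vals, k=2.5)
        assert flags25[-1] and flags25[:-1].sum() == 0

    def test_germination_style_single_removal(self):
        vals = [1.0] * 15 + [0.99] * 2 + [0.15]  # one wildly low replicate
        retained, flags = screen_outliers(vals, k=4)
        assert flags.sum() == 1
        assert len(retained) == 17

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            screen_outliers([1.0, 2.0])


class TestBonferroniCutoff:
    def test_single_test_is_1_96(self):
        assert bonferroni_cutoff(0.05, 1) == pytest.approx(1.96, abs=0.005)

    def test_hundred_line_family_is_3_48(self):
        assert round(bonferroni_cutoff(0.05, 100), 2) == 3.48

    @given(m=st.integers(1, 500))
    def test_monotone_in_family_size(self, m):
        assert bonferroni_cutoff(0.05, m + 1) > bonferroni_cutoff(0.05, m)


class TestClassifyLines:
    def test_line_at_ancestor_mean_is_none(self):
        table = make_table(anc=[1.0, 1.02, 0.98], ma=[1.0])
        calls, _ = classify_lines(table, "liquid_growth", cutoff=3.48)
        assert calls[0].direction == "none"

    def test_hand_arithmetic_low_call(self):
        rng = np.random.default_rng(0)
        anc = 1.0 + 0.03 * np.array([1, -1, 0.5, -0.5, 0.25, -0.25]) * (6 / 2.625) ** 0.5
        table = make_table(anc=list(anc), ma=[0.85, 1.0])
        calls, bounds = classify_lines(table, "liquid_growth", cutoff=3.48)
        by_val = {round(c.z_score, 1): c.direction for c in calls}
        low = [c for c in calls if c.direction == "low"]
        assert len(low) == 1  # z of 0.85 is about -5

    def test_bounds_formula(self):
        table = make_table(anc=[1.1, 0.9, 1.0, 1.0], ma=[1.0])
        calls, (lo, hi) = classify_lines(table, "liquid_growth", cutoff=2.0)
        sd = np.std([1.1, 0.9, 1.0, 1.0], ddof=1)
        assert lo == pytest.approx(1.0 - 2 * sd)
        assert hi == pytest.approx(1.0 + 2 * sd)

    def test_zero_ancestor_sd_flags_deviants(self):
        table = make_table(anc=[1.0, 1.0, 1.0], ma=[0.9, 1.0, 1.1])
        with pytest.warns(UserWarning, match="degenerate"):
            calls, bounds = classify_lines(table, "liquid_growth", cutoff=3.48)
        dirs = {c.line_id: c.direction for c in calls}
        assert sorted(dirs.values()) == ["high", "low", "none"]

    def test_exceedance_converges_to_normal_tail(self, rng):
        # with cutoff z and normal line values, P(flag) = 2*(1-Phi(z))
        cutoff = 2.0
        anc = list(rng.normal(1, 0.05, 500))
        ma = list(rng.normal(1, 0.05, 4000))
        table = make_table(anc=anc, ma=ma)
        calls, _ = classify_lines(table, "liquid_growth", cutoff=cutoff)
        low, high = count_calls(calls)
        expected = 2 * stats.norm.sf(cutoff) * len(ma)
        assert low + high == pytest.approx(expected, rel=0.35)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03], "benjamini_hochberg")[0] == pytest.approx(0.03)

    def test_bh_step_up_by_hand(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03], "benjamini_hochberg")
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_bonferroni_multiplies_and_clips(self):
        adj = adjust_pvalues([0.01, 0.01, 0.01], "bonferroni")
        assert np.allclose(adj, 0.03)
        assert adjust_pvalues([0.9, 0.9], "bonferroni").max() == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_never_below_raw(self, ps):
        adj = adjust_pvalues(ps, "benjamini_hochberg")
        assert np.all(adj >= np.asarray(ps) - 1e-12)
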