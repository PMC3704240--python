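import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from mafitkit.pleiotropy import (
    adhoc_lower_bound_U,
    component_rate,
    cubic_optimum,
    effective_traits,
    expected_affected_distribution,
    randomization_test_A,
    randomization_test_B,
    spearman_matrix,
)

# per-trait counts of significantly altered MA lines (low + high), the
# observed significance structure driving the randomization tests
K_SIG = np.array([2, 68, 48, 17, 43, 77, 85, 61])
N_LINES = 90
G = 994


class TestSpearman:
    def test_monotone_pairs(self):
        df = pd.DataFrame({
            "plate_growth": [1, 2, 3, 4, 5, 6],
            "liquid_growth": [2, 4, 9, 16, 25, 36],
            "slug_distance": [6, 5, 4, 3, 2, 1],
        })
        corr, _ = spearman_matrix(df)
        assert corr.loc["plate_growth", "liquid_growth"] == pytest.approx(1.0)
        assert corr.loc["plate_growth", "slug_distance"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_hand_rank_formula(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        df = pd.DataFrame({"plate_growth": x, "liquid_growth": y})
        corr, _ = spearman_matrix(df)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expect = 1 - 6 * np.sum((rx - ry) ** 2) / (6 * 35)
        assert corr.iloc[0, 1] == pytest.approx(expect)

    def test_constant_trait_flagged_nan(self):
        df = pd.DataFrame({"plate_growth": [1.0, 1, 1, 1, 1],
                           "liquid_growth": [1, 2, 3, 4, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            corr, _ = spearman_matrix(df)
        assert math.isnan(corr.loc["plate_growth", "liquid_growth"])


class TestEffectiveTraits:
    def test_identity_matrix_full_independence(self):
        _, v, n_eff = effective_traits(np.eye(8))
        assert v == 0.0
        assert n_eff == 8.0

    def test_all_ones_perfect_dependence(self):
        lam, v, n_eff = effective_traits(np.ones((5, 5)))
        assert n_eff == pytest.approx(1.0)
        assert sorted(np.round(lam, 9))[-1] == pytest.approx(5.0)

    def test_eigenvalues_sum_to_n(self, rng):
        A = rng.normal(size=(40, 8))
        C = np.corrcoef(A.T)
        lam, _, _ = effective_traits(C)
        assert lam.sum() == pytest.approx(8.0)

    def test_permutation_invariance(self, rng):
        A = rng.normal(size=(40, 6))
        C = np.corrcoef(A.T)
        _, _, n0 = effective_traits(C)
        perm = rng.permutation(6)
        _, _, n1 = effective_traits(C[np.ix_(perm, perm)])
        assert n0 == pytest.approx(n1)

    def test_stronger_correlation_lowers_n_eff(self):
        def two_trait(r):
            return effective_traits(np.array([[1.0, r], [r, 1.0]]))[2]
        assert two_trait(0.8) < two_trait(0.4) < two_trait(0.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            effective_traits(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestComponentRate:
    def test_zero_significant_zero_rate(self):
        r = component_rate("plate_growth", 0, N_LINES, G)
        assert r.mu_hat == 0.0

    def test_log_arithmetic(self):
        # k = 85 of 90: lambda ~ -ln(5/90) up to the discrete correction
        r = component_rate("spore_germination", 85, N_LINES, G)
        assert r.lambda_hat == pytest.approx(-math.log(5 / 90), rel=0.005)

    def test_inverse_consistency(self):
        for k in (0, 1, 17, 43, 85):
            r = component_rate("t", k, N_LINES, G)
            assert (1 - r.mu_hat) ** G * N_LINES == pytest.approx(N_LINES - k, abs=1e-9)

    def test_all_lines_affected_unbounded(self):
        with pytest.warns(UserWarning, match="unbounded"):
            r = component_rate("t", N_LINES, N_LINES, G)
        assert r.unbounded and math.isnan(r.mu_hat)


class TestExpectedDistribution:
    def test_all_zero_probabilities(self):
        e = expected_affected_distribution(np.zeros(8), N_LINES)
        assert e[0] == N_LINES
        assert np.all(e[1:] == 0)

    def test_sums_to_n_lines(self):
        e = expected_affected_distribution(K_SIG / N_LINES, N_LINES)
        assert e.sum() == pytest.approx(N_LINES)

    def test_matches_independent_binomial_convolution(self, rng):
        p = rng.random(5)
        e = expected_affected_distribution(p, 1)
        # brute force over all 2^5 outcomes
        brute = np.zeros(6)
        for mask in range(32):
            prob = 1.0
            for i in range(5):
                prob *= p[i] if (mask >> i) & 1 else 1 - p[i]
            brute[bin(mask).count("1")] += prob
        assert np.allclose(e, brute)


class TestRandomizationTests:
    def test_a_degenerate_all_zero(self):
        res = randomization_test_A(np.zeros(8, int), N_LINES, n_sims=200, seed=1)
        assert res.n_significant_sims == 0
        assert np.all(res.sim_mean_counts[1:] == 0)

    def test_a_mean_counts_converge_to_analytic(self):
        res = randomization_test_A(K_SIG, N_LINES, n_sims=2000, seed=3)
        expected = expected_affected_distribution(K_SIG / N_LINES, N_LINES)
        se = np.sqrt(np.maximum(expected, 0.05) / 2000) * 3
        # category-wise agreement within 3 Monte-Carlo SEs (plus slack for
        # the without-replacement dependence across traits)
        assert np.all(np.abs(res.sim_mean_counts - expected) < se + 0.35)

    def test_b_mean_counts_match_poisson_binomial(self):
        rates = [component_rate(str(i), int(k), N_LINES, G) for i, k in enumerate(K_SIG)]
        res = randomization_test_B(rates, N_LINES, n_sims=2000, seed=4)
        lam = np.array([r.lambda_hat for r in rates])
        expected = expected_affected_distribution(1 - np.exp(-lam), N_LINES)
        se = np.sqrt(np.maximum(expected, 0.05) / 2000) * 3
        assert np.all(np.abs(res.sim_mean_counts - expected) < se + 0.3)

    def test_b_zero_rates_degenerate(self):
        rates = [component_rate(str(i), 0, N_LINES, G) for i in range(8)]
        res = randomization_test_B(rates, N_LINES, n_sims=200, seed=5)
        assert res.sim_mean_counts[0] == N_LINES

    def test_observed_chi2_reported(self):
        obs = np.array([0, 1, 4, 13, 24, 34, 11, 3, 0])
        res = randomization_test_A(K_SIG, N_LINES, n_sims=200, seed=6,
                                   observed_counts=obs)
        assert res.df == 8
        assert res.chi2 > 0
        assert 0 <= res.p_value <= 1

    def test_low_sims_warn(self):
        with pytest.warns(UserWarning, match="unstable"):
            randomization_test_A(K_SIG, N_LINES, n_sims=50, seed=7)


class TestAdhocBound:
    def test_single_line_reduction(self):
        out = adhoc_lower_bound_U(1, G, confidence=0.95)
        # strict reading: 1 - e^{-UG} = 0.05
        assert out["strict"] * G == pytest.approx(-math.log(0.95), rel=1e-6)

    def test_both_readings_against_root_finding(self):
        out = adhoc_lower_bound_U(90, G)
        f1 = lambda ug: (1 - math.exp(-ug)) ** 90 - 0.05
        f2 = lambda ug: (1 - math.exp(-ug)) ** 90 - 0.95
        assert out["strict"] * G == pytest.approx(optimize.brentq(f1, 1e-9, 50), rel=1e-9)
        assert out["attained"] * G == pytest.approx(optimize.brentq(f2, 1e-9, 50), rel=1e-9)
        assert out["strict"] * G == pytest.approx(3.42, abs=0.01)
        assert out["attained"] * G == pytest.approx(7.47, abs=0.01)


class TestCubicOptimum:
    def test_parabola_symmetry(self):
        x = np.linspace(0, 2, 21)
        y = -((x - 1.0) ** 2)
        fit = cubic_optimum(x, y)
        assert fit.optimum == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_cubic_stationary_points(self):
        # y = x^3 - 3x: local max at -1, local min at +1
        x = np.linspace(-2, 2, 25)
        fit = cubic_optimum(x, x ** 3 - 3 * x)
        assert fit.optimum == pytest.approx(-1.0, abs=1e-6)
        assert fit.p_value < 1e-6

    def test_no_interior_maximum_reported_absent(self):
        x = np.linspace(0, 1, 15)
        fit = cubic_optimum(x, 2 * x + 0.001 * x ** 3)
        assert fit.optimum is None

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cubic_optimum([1, 2, 3], [1, 2, 3])
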