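import math

import numpy as np
import pytest
from scipy import stats

from mafitkit.ml_effects import (
    LikelihoodSettings,
    MutationEffectsModel,
    SupportInterval,
    effect_sum_density,
    fit_equal_effects,
    fit_ml,
    k_truncation,
    line_density,
    line_loglik,
    support_interval,
)
from mafitkit.simulate import MutationModelParams, draw_line_effects, params_for_mean_effect

FAST = LikelihoodSettings(
    beta_grid=(0.5, 1, 2, 4, 10), P_grid=(0.0, 0.1, 0.2, 0.3, 0.5),
    refine_rounds=0, n_starts=2, maxiter=120,
    profile_points=9, profile_span_decades=2.0)


def simulate_lines(params, n, rng, equal_effect=None):
    counts = rng.poisson(params.M, n)
    if equal_effect is None:
        mags = rng.gamma(params.beta, 1 / params.alpha, counts.sum())
    else:
        mags = np.full(counts.sum(), equal_effect)
    signs = np.where(rng.random(counts.sum()) < params.P, 1.0, -1.0)
    sums = np.bincount(np.repeat(np.arange(n), counts),
                       weights=signs * mags, minlength=n)
    return 1 + sums + rng.normal(0, params.sigma_env, n)


class TestEffectSumDensity:
    GRID = np.linspace(-3, 3, 2401)

    def test_single_deleterious_is_mirrored_gamma(self):
        d = effect_sum_density(1, 0, alpha=5.0, beta=1.0, grid=self.GRID)
        neg = self.GRID < 0
        assert np.allclose(d[neg], stats.gamma.pdf(-self.GRID[neg], a=1, scale=0.2))
        assert np.all(d[self.GRID > 0] == 0)

    def test_single_beneficial_is_plain_gamma(self):
        d = effect_sum_density(1, 1, alpha=5.0, beta=2.0, grid=self.GRID)
        pos = self.GRID > 0
        assert np.allclose(d[pos], stats.gamma.pdf(self.GRID[pos], a=2, scale=0.2))

    def test_exponential_difference_is_laplace(self):
        # X - Y with X, Y ~ Exp(alpha) is Laplace with rate alpha
        alpha = 4.0
        d = effect_sum_density(2, 1, alpha=alpha, beta=1.0, grid=self.GRID)
        expect = 0.5 * alpha * np.exp(-alpha * np.abs(self.GRID))
        assert np.max(np.abs(d - expect)) < 0.01 * expect.max()

    def test_matches_monte_carlo_histogram(self, rng):
        alpha, beta = 5.0, 1.0
        d = effect_sum_density(3, 1, alpha=alpha, beta=beta, grid=self.GRID)
        draws = (rng.gamma(beta, 1 / alpha, 10 ** 6)
                 - rng.gamma(2 * beta, 1 / alpha, 10 ** 6))
        hist, edges = np.histogram(draws, bins=120, range=(-3, 3), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        interp = np.interp(centers, self.GRID, d)
        assert np.max(np.abs(hist - interp)) < 0.01 * d.max() + 0.05

    def test_integrates_to_one(self):
        for k, j in [(1, 0), (1, 1), (2, 1), (4, 1), (5, 3)]:
            d = effect_sum_density(k, j, alpha=5.0, beta=1.0, grid=self.GRID)
            assert np.trapezoid(d, self.GRID) == pytest.approx(1.0, abs=1e-4)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            effect_sum_density(0, 0, 1.0, 1.0, self.GRID)
        with pytest.raises(ValueError):
            effect_sum_density(2, 1, -1.0, 1.0, self.GRID)


class TestLineDensity:
    def test_U_zero_reduces_to_normal(self):
        p = MutationModelParams(U=0.0, alpha=6.67, beta=1.0, sigma_env=0.03)
        z = np.array([0.9, 1.0, 1.1])
        assert np.allclose(line_loglik(z, p), stats.norm.logpdf(z, 1, 0.03))

    def test_tiny_U_close_to_normal(self):
        p = MutationModelParams(U=1e-9, alpha=6.67, beta=1.0, sigma_env=0.03)
        z = np.array([0.9, 1.0, 1.1])
        assert np.allclose(line_loglik(z, p), stats.norm.logpdf(z, 1, 0.03),
                           atol=1e-4)

    @pytest.mark.parametrize("M,beta,P", [(2.0, 1.0, 0.3), (0.5, 2.0, 0.0),
                                          (4.0, 0.5, 0.5)])
    def test_density_normalizes(self, M, beta, P):
        p = MutationModelParams(U=M / 994, alpha=beta / 0.15, beta=beta,
                                sigma_env=0.03, P=P)
        z = np.linspace(1 - 6, 1 + 6, 12001)
        f = line_density(z, p)
        assert np.trapezoid(f, z) == pytest.approx(1.0, abs=1e-4)

    def test_matches_monte_carlo_oracle(self, rng):
        p = params_for_mean_effect(U=0.002, mean_effect=0.15, P=0.1,
                                   sigma_env=0.03)
        n = 10 ** 6
        zs = simulate_lines(p, n, rng)
        for a, b in [(0.55, 0.65), (0.75, 0.85), (0.95, 1.05),
                     (1.05, 1.15), (1.15, 1.25)]:
            grid = np.linspace(a, b, 101)
            analytic = np.trapezoid(line_density(grid, p), grid)
            mc = np.mean((zs > a) & (zs < b))
            se = math.sqrt(mc * (1 - mc) / n)
            assert analytic == pytest.approx(mc, abs=4 * se + 2e-4)

    def test_finite_for_extreme_values(self):
        p = params_for_mean_effect(U=0.002, mean_effect=0.15, sigma_env=0.03)
        ll = line_loglik(np.array([-5.0, 8.0]), p)
        assert np.all(np.isfinite(ll))

    def test_k_truncation_rule(self):
        assert k_truncation(0.0) == 0
        k = k_truncation(2.0, tail=1e-10, cap=60)
        assert stats.poisson.sf(k, 2.0) < 1e-10
        assert stats.poisson.sf(k - 2, 2.0) > 1e-10
        with pytest.warns(UserWarning, match="cap"):
            assert k_truncation(500.0, cap=60) == 60


class TestSupportInterval:
    def test_quadratic_profile_closed_form(self):
        # -(x - 3)^2 / (2 s^2) drops by 2 at x = 3 +/- 2s
        s = 0.5
        x = np.linspace(0, 6, 601)
        ll = -((x - 3.0) ** 2) / (2 * s ** 2)
        si = support_interval(x, ll, drop=2.0)
        assert si.lower == pytest.approx(3 - 2 * s, abs=0.01)
        assert si.upper == pytest.approx(3 + 2 * s, abs=0.01)
        assert not si.open_lower and not si.open_upper

    def test_monotone_profile_open_upper(self):
        x = np.linspace(0, 1, 50)
        si = support_interval(x, 3 * x, drop=2.0)
        assert si.open_upper
        assert not si.open_lower

    def test_point_estimate_inside(self, rng):
        x = np.sort(rng.random(30)) + 0.1
        ll = -((x - x[13]) ** 2) * 20
        si = support_interval(x, ll, drop=2.0)
        assert si.lower <= x[np.argmax(ll)] <= si.upper

    def test_flat_profile_warns_both_open(self):
        with pytest.warns(UserWarning, match="flat"):
            si = support_interval([1, 2, 3], [0.0, 0.0, 0.0])
        assert si.open_lower and si.open_upper


class TestFit:
    def test_parameter_recovery_single_replicate(self, rng):
        p = params_for_mean_effect(U=0.002, mean_effect=0.15, beta=1.0,
                                   P=0.1, sigma_env=0.03)
        lines = simulate_lines(p, 90, rng)
        anc = 1 + rng.normal(0, 0.03, 16)
        res = fit_ml(anc, lines, G=994, settings=FAST)
        assert np.isfinite(res.loglik)
        assert res.support_intervals["U"].contains(0.002)
        assert res.support_intervals["E_a"].contains(0.15)
        # sigma is anchored by the ancestor replicates
        assert res.params_hat.sigma_env == pytest.approx(0.03, rel=0.5)

    def test_null_data_pushes_U_to_zero(self, rng):
        anc = 1 + rng.normal(0, 0.03, 16)
        lines = 1 + rng.normal(0, 0.03, 40)
        res = fit_ml(anc, lines, G=994, settings=FAST)
        si = res.support_intervals["U"]
        assert si.open_lower  # lower end at the search floor, reported as 0
        assert res.params_hat.M < 1.0

    def test_profile_covers_requested_grid(self, rng):
        p = params_for_mean_effect(U=0.002, mean_effect=0.15, sigma_env=0.03)
        lines = simulate_lines(p, 90, rng)
        anc = 1 + rng.normal(0, 0.03, 16)
        small = LikelihoodSettings(beta_grid=(1.0, 2.0), P_grid=(0.0, 0.2),
                                   refine_rounds=0, n_starts=1, maxiter=80,
                                   profile_points=5, profile_span_decades=1.5)
        res = fit_ml(anc, lines, G=994, settings=small)
        cells = {(r.beta, r.P) for r in res.profile.itertuples()}
        assert {(1.0, 0.0), (1.0, 0.2), (2.0, 0.0), (2.0, 0.2)} <= cells

    def test_input_validation(self):
        with pytest.raises(ValueError, match="ancestor"):
            MutationEffectsModel([1.0] * 3, [1.0] * 20)
        with pytest.raises(ValueError, match="lines"):
            MutationEffectsModel([1.0] * 8, [1.0] * 5)


class TestEqualEffects:
    def test_wins_on_equal_effects_data(self, rng):
        p = params_for_mean_effect(U=0.003, mean_effect=0.12, beta=1.0,
                                   P=0.0, sigma_env=0.02)
        lines = simulate_lines(p, 90, rng, equal_effect=0.12)
        anc = 1 + rng.normal(0, 0.02, 16)
        res_eq = fit_equal_effects(anc, lines, G=994, settings=FAST)
        res_gamma = fit_ml(anc, lines, G=994, settings=FAST)
        assert res_eq.loglik >= res_gamma.loglik - 1.0
        assert res_eq.effect_size == pytest.approx(0.12, rel=0.35)
        assert res_eq.support_intervals["P"].contains(0.0)

    def test_recovers_rate(self, rng):
        p = params_for_mean_effect(U=0.003, mean_effect=0.12, beta=1.0,
                                   P=0.0, sigma_env=0.02)
        lines = simulate_lines(p, 90, rng, equal_effect=0.12)
        anc = 1 + rng.normal(0, 0.02, 16)
        res = fit_equal_effects(anc, lines, G=994, settings=FAST)
        assert res.U == pytest.approx(0.003, rel=0.5)
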