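"""Pleiotropy analyses: trait correlation structure, effective number of
traits, per-component mutation rates, and randomization tests of
independence.

If mutations tend to act on single fitness components, the per-line counts
of significantly altered components should match what independent
per-component mutation predicts.  Two null simulations formalize this:
test A shuffles the observed per-trait significance labels across lines;
test B draws per-line per-trait Poisson mutation counts at rates inverted
from the fraction of unaffected lines, (1 - mu_i)^G = (n - k_i)/n.  Both
nulls share the analytic Poisson-binomial distribution of per-line affected
counts as their large-simulation limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.anova import anova_lm

from .groupstats import adjust_pvalues

CHI2_CATEGORIES = 9  # affected-component counts 0..8 for eight traits


@dataclass(frozen=True)
class ComponentRate:
    """Per-component mutation rate inverted from the unaffected fraction."""

    trait: str
    k_sig: int
    n_lines: int
    G: int
    mu_hat: float  # per-generation rate
    lambda_hat: float  # expected mutations per line, G * mu_hat
    unbounded: bool = False


@dataclass
class PleiotropyResult:
    """Bundle of pleiotropy diagnostics; randomization tests fill the count
    fields, the full analysis also fills the correlation fields."""

    observed_counts: np.ndarray | None = None
    expected_counts: np.ndarray | None = None
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None
    n_sims: int | None = None
    n_significant_sims: int | None = None
    sim_mean_counts: np.ndarray | None = None
    spearman: pd.DataFrame | None = None
    spearman_p_adjusted: pd.DataFrame | None = None
    eigenvalues: np.ndarray | None = None
    var_lambda: float | None = None
    n_eff: float | None = None
    affected_counts: pd.Series | None = None

    @property
    def significant_fraction(self) -> float | None:
        if self.n_sims and self.n_significant_sims is not None:
            return self.n_significant_sims / self.n_sims
        return None


def spearman_matrix(line_means: pd.DataFrame):
    """Pairwise Spearman correlations (midranks) among traits.

    Parameters
    ----------
    line_means : DataFrame, lines x traits.

    Returns
    -------
    (corr, p_adj) : (DataFrame, DataFrame)
        Symmetric correlation matrix with unit diagonal and BH-adjusted
        p-values (diagonal NaN).  A constant trait's correlations are NaN
        and a warning is raised.
    """
    if line_means.shape[0] < 4:
        raise ValueError("need >= 4 complete lines")
    X = line_means.to_numpy(float)
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant traits, correlations undefined: "
            f"{list(line_means.columns[constant])}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(X)
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[np.nan, p], [p, np.nan]])
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    cols = line_means.columns
    iu = np.triu_indices(len(cols), k=1)
    p_off = np.asarray(p)[iu]
    ok = np.isfinite(p_off)
    adj = np.full_like(p_off, np.nan)
    adj[ok] = adjust_pvalues(p_off[ok], "benjamini_hochberg")
    p_adj = np.full((len(cols), len(cols)), np.nan)
    p_adj[iu] = adj
    p_adj.T[iu] = adj
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p_adj, index=cols, columns=cols))


def effective_traits(corr, ddof: int = 0):
    """Effective number of traits from eigenvalue dispersion.

    N_eff = N - Var(lambda) where lambda are the eigenvalues of the trait
    correlation matrix.  Their mean is exactly 1, so Var uses divisor N by
    default (``ddof`` exposed).  N_eff equals N for independent traits and
    1 under perfect correlation.

    Returns
    -------
    (eigenvalues, var_lambda, n_eff)
    """
    C = np.asarray(corr, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(C)
    var_lambda = float(np.var(lam, ddof=ddof))
    return lam, var_lambda, float(C.shape[0] - var_lambda)


def component_rate(trait: str, k_sig: int, n_lines: int, G: int) -> ComponentRate:
    """Invert the mutation-free fraction: (1 - mu)^G = (n - k)/n."""
    if not 0 <= k_sig <= n_lines:
        raise ValueError("k_sig must be in [0, n_lines]")
    if k_sig == n_lines:
        warnings.warn(f"{trait}: every line affected; rate unbounded")
        return ComponentRate(trait=trait, k_sig=k_sig, n_lines=n_lines, G=G,
                             mu_hat=math.nan, lambda_hat=math.nan, unbounded=True)
    mu = 1.0 - ((n_lines - k_sig) / n_lines) ** (1.0 / G)
    return ComponentRate(trait=trait, k_sig=k_sig, n_lines=n_lines, G=G,
                         mu_hat=mu, lambda_hat=G * mu)


def expected_affected_distribution(p, n_lines: int) -> np.ndarray:
    """Expected count of lines with 0..N affected components, from the exact
    Poisson-binomial pmf under trait independence (the analytic limit of
    both randomization tests)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return n_lines * pmf


def _chi2_vs_expectation(counts, expected):
    """Pearson chi-square of category counts against a fixed expectation,
    all categories kept (no pooling)."""
    counts = np.asarray(counts, float)
    expected = np.asarray(expected, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    terms = np.where((expected == 0) & (counts == 0), 0.0, terms)
    return float(np.sum(np.where(np.isfinite(terms), terms, np.inf)))


def _randomization_result(sim_counts, observed, expected, n_sims):
    df = len(expected) - 1
    crit = stats.chi2.isf(0.05, df)
    chi_sims = np.array([_chi2_vs_expectation(c, expected) for c in sim_counts])
    n_sig = int(np.sum(chi_sims > crit))
    chi_obs = None
    p_obs = None
    if observed is not None:
        chi_obs = _chi2_vs_expectation(observed, expected)
        p_obs = float(stats.chi2.sf(chi_obs, df))
    return PleiotropyResult(
        observed_counts=None if observed is None else np.asarray(observed),
        expected_counts=expected, chi2=chi_obs, df=df, p_value=p_obs,
        n_sims=n_sims, n_significant_sims=n_sig,
        sim_mean_counts=sim_counts.mean(axis=0))


def randomization_test_A(k_sig, n_lines: int, n_sims: int = 1000,
                         seed: int | None = None,
                         observed_counts=None) -> PleiotropyResult:
    """Label-shuffling null: each trait's k_sig significant labels are
    reassigned uniformly without replacement across lines; per-line affected
    counts are tallied and each simulated tally is chi-square-tested against
    the independence expectation (Poisson-binomial with p_i = k_i/n).

    ``k_sig`` may be a sequence of per-trait counts or a table of
    SignificanceCall objects (counted per trait).
    """
    k = _coerce_k(k_sig)
    if n_sims < 100:
        warnings.warn("n_sims < 100: tail fraction estimate unstable")
    rng = np.random.default_rng(seed)
    n_traits = len(k)
    expected = expected_affected_distribution(k / n_lines, n_lines)
    sim_counts = np.empty((n_sims, n_traits + 1), int)
    for s in range(n_sims):
        affected = np.zeros(n_lines, int)
        for ki in k:
            affected[rng.choice(n_lines, int(ki), replace=False)] += 1
        sim_counts[s] = np.bincount(affected, minlength=n_traits + 1)
    return _randomization_result(sim_counts, observed_counts, expected, n_sims)


def randomization_test_B(rates, n_lines: int, n_sims: int = 1000,
                         seed: int | None = None,
                         observed_counts=None) -> PleiotropyResult:
    """Poisson-mutation null: per simulation, line and trait, a mutation
    count is drawn Poisson(lambda_i) and the trait counted affected when at
    least one mutation occurred; tallies are tested as in test A."""
    lam = np.array([r.lambda_hat for r in rates], float)
    if np.isnan(lam).any():
        raise ValueError("unbounded component rate: cannot simulate")
    if n_sims < 100:
        warnings.warn("n_sims < 100: tail fraction estimate unstable")
    rng = np.random.default_rng(seed)
    n_traits = len(lam)
    expected = expected_affected_distribution(1.0 - np.exp(-lam), n_lines)
    sim_counts = np.empty((n_sims, n_traits + 1), int)
    for s in range(n_sims):
        m = rng.poisson(lam, size=(n_lines, n_traits))
        affected = (m > 0).sum(axis=1)
        sim_counts[s] = np.bincount(affected, minlength=n_traits + 1)
    return _randomization_result(sim_counts, observed_counts, expected, n_sims)


def _coerce_k(k_sig) -> np.ndarray:
    try:
        return np.asarray([int(k) for k in k_sig])
    except (TypeError, ValueError):
        pass
    by_trait: dict[str, int] = {}
    for call in k_sig:
        by_trait.setdefault(call.trait, 0)
        if call.direction != "none":
            by_trait[call.trait] += 1
    return np.asarray([by_trait[t] for t in sorted(by_trait)])


def affected_counts_per_line(calls) -> pd.Series:
    """Per-line count of significantly altered components from a flat list
    of SignificanceCall objects."""
    rows = {}
    for c in calls:
        rows.setdefault(c.line_id, 0)
        if c.direction != "none":
            rows[c.line_id] += 1
    return pd.Series(rows).sort_index()


def adhoc_lower_bound_U(n_lines: int, G: int, confidence: float = 0.95) -> dict:
    """Ad-hoc lower bound on U from every line carrying >= 1 mutation.

    The stated procedure — the rate at which the probability of obtaining
    zero mutation-free lines among n is less than 5% — admits two readings
    of "probability ... less than 5%", and both are solved and returned:

    - ``strict``: P(no mutation-free line) = 1 - confidence
      ((1 - e^{-UG})^n = 0.05), the smallest rate making the all-mutated
      outcome merely possible at the 5% level;
    - ``attained``: P(no mutation-free line) = confidence
      ((1 - e^{-UG})^n = 0.95), the rate making the observed all-mutated
      outcome probable.
    """
    out = {}
    for name, target in (("strict", 1.0 - confidence), ("attained", confidence)):
        f = lambda ug: (1.0 - math.exp(-ug)) ** n_lines - target
        ug = optimize.brentq(f, 1e-9, 100.0)
        out[name] = ug / G
    return out


@dataclass(frozen=True)
class CubicFit:
    """Least-squares cubic with a stabilizing-selection diagnostic."""

    coefficients: np.ndarray  # ascending powers
    f_stat: float
    p_value: float  # cubic model vs linear, F-test
    optimum: float | None  # interior local maximum, if any


def cubic_optimum(x, y) -> CubicFit:
    """Fit y = b0 + b1 x + b2 x^2 + b3 x^3 and locate an interior local
    maximum of the fitted curve within the data range (absent -> None).
    The F-test compares the cubic against the linear model."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 8:
        raise ValueError("need >= 8 points")
    X_lin = sm.add_constant(x)
    X_cub = sm.add_constant(np.column_stack([x, x ** 2, x ** 3]))
    fit_lin = sm.OLS(y, X_lin).fit()
    fit_cub = sm.OLS(y, X_cub).fit()
    an = anova_lm(fit_lin, fit_cub)
    f_stat = float(an["F"].iloc[1])
    p = float(an["Pr(>F)"].iloc[1])
    b = fit_cub.params  # const, x, x^2, x^3
    coef = np.asarray(b, float)
    # stationary points of the cubic: 3 b3 t^2 + 2 b2 t + b1 = 0
    der = np.polynomial.polynomial.Polynomial([coef[1], 2 * coef[2], 3 * coef[3]])
    second = np.polynomial.polynomial.Polynomial([2 * coef[2], 6 * coef[3]])
    optimum = None
    roots = der.roots()
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        t = float(r.real)
        if x.min() <= t <= x.max() and second(t) < 0:
            optimum = t
    return CubicFit(coefficients=coef, f_stat=f_stat, p_value=p, optimum=optimum)


def pleiotropy_analysis(line_means: pd.DataFrame, calls, n_lines: int,
                        G: int, n_sims: int = 1000,
                        seed: int | None = None) -> PleiotropyResult:
    """Full pleiotropy bundle: Spearman matrix, N_eff, per-line affected
    counts, both randomization tests, and the observed-vs-expected test."""
    corr, p_adj = spearman_matrix(line_means)
    lam, var_lambda, n_eff = effective_traits(corr.to_numpy())
    per_line = affected_counts_per_line(calls)
    n_traits = line_means.shape[1]
    observed = np.bincount(per_line.to_numpy(), minlength=n_traits + 1)
    k = _coerce_k(calls)
    rates = [component_rate(t, int(ki), n_lines, G)
             for t, ki in zip(sorted({c.trait for c in calls}), k)]
    res_a = randomization_test_A(k, n_lines, n_sims, seed, observed_counts=observed)
    res_b = randomization_test_B(rates, n_lines, n_sims,
                                 None if seed is None else seed + 1,
                                 observed_counts=observed)
    result = res_b
    result.spearman = corr
    result.spearman_p_adjusted = p_adj
    result.eigenvalues = lam
    result.var_lambda = var_lambda
    result.n_eff = n_eff
    result.affected_counts = per_line
    result.test_a = res_a  # type: ignore[attr-defined]
    return result
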