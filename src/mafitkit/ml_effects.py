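"""Maximum-likelihood estimation of mutation parameters from MA line means.

Model.  A line accumulates k ~ Poisson(M) mutations over the MA phase,
M = U*G.  Each mutation's effect is drawn from a gamma distribution with
shape beta and rate alpha, reflected around zero: positive with probability
P, negative otherwise; E(a) = beta/alpha is the mean absolute effect.  The
observed line mean is z = 1 + sum(effects) + Normal(0, sigma_env^2), and
ancestor replicates are mutation-free draws Normal(1, sigma_env^2).  The
line-mean density is the Poisson-binomial mixture

    f(z) = sum_k Pois(k; M) sum_j Binom(j; k, P)
           [gamma-difference(j*beta, (k-j)*beta; alpha) * N(0, sigma^2)](z - 1)

with the k = 0 term a plain normal.  The (k, j) sum collapses in Fourier
space: the characteristic function of the summed effect is c(t)^k with
c(t) = P (1 - it/alpha)^(-beta) + (1 - P) (1 + it/alpha)^(-beta), so the
truncated mixture CF is sum_{k<=kmax} Pois(k; M) c(t)^k times the Gaussian
noise CF, inverted by trapezoidal quadrature at the observed values.  The
Poisson truncation kmax is the smallest k whose upper tail mass is below a
threshold, capped.

Fitting follows a grid-profile procedure: for each (beta, P) on a fixed
grid the likelihood is maximized over (U, alpha, sigma_env) [on log scales,
Nelder-Mead from deterministic starts], the grid is refined around the best
cell, and 2-log-unit support intervals are read off one-dimensional
profiles.  Likelihood surfaces in MA data are often ridged — many tiny
effects and few large ones fit equally well — so interval endpoints hitting
the search bounds are flagged open (reported as 0 or infinity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import MutationModelParams

LOG_U_BOUNDS = (math.log(1e-8), math.log(0.5))
LOG_ALPHA_BOUNDS = (math.log(1e-3), math.log(1e6))
DENSITY_FLOOR = 1e-280


@dataclass
class LikelihoodSettings:
    """Numerical settings for the likelihood machinery.

    k truncation keeps Poisson tail mass below ``poisson_tail`` (hard cap
    ``k_cap``).  The Fourier quadrature step is 2*pi/L where the aliasing
    period L spans the data plus ``alias_allowance`` (trapezoidal CF
    inversion equals the Fourier series of the L-periodized density, so L
    must cover the density's effective support); the grid extends until the
    Gaussian noise factor at the smallest admissible sigma is negligible.
    """

    poisson_tail: float = 1e-10
    k_cap: int = 60
    beta_grid: tuple = (0.1, 0.5, 1, 2, 3, 4, 6, 8, 10, 50)
    P_grid: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    refine_rounds: int = 1
    n_starts: int = 3
    maxiter: int = 150
    xatol: float = 1e-3
    fatol: float = 1e-4
    alias_allowance: float = 12.0
    sigma_floor_factor: float = 0.25  # times the ancestor SD
    sigma_floor_abs: float = 1e-4
    profile_points: int = 13
    profile_span_decades: float = 2.5
    support_drop: float = 2.0

    def __post_init__(self):
        if not self.beta_grid or not self.P_grid:
            raise ValueError("parameter grids must be nonempty")
        if self.poisson_tail >= 1e-6:
            raise ValueError("poisson_tail must keep truncation below 1e-6")


def k_truncation(M: float, tail: float = 1e-10, cap: int = 60) -> int:
    """Smallest k with Poisson(M) upper-tail mass below ``tail``, capped."""
    if M <= 0:
        return 0
    k = int(stats.poisson.isf(tail, M)) + 1
    if k > cap:
        warnings.warn("k truncation cap hit; density biased for very large "
                      "expected mutation numbers")
        return cap
    return k


def _reflected_gamma_cf(t, alpha, beta, P):
    """CF of a single reflected-gamma effect."""
    base_pos = (1.0 - 1j * t / alpha) ** (-beta)
    base_neg = (1.0 + 1j * t / alpha) ** (-beta)
    return P * base_pos + (1.0 - P) * base_neg


def _mixture_cf(t, M, P, alpha, beta, kmax):
    """Truncated compound-Poisson CF: sum_{k<=kmax} Pois(k; M) c(t)^k."""
    if M <= 0 or kmax == 0:
        return np.ones_like(t, dtype=complex) * math.exp(-M) if M > 0 else np.ones_like(t, dtype=complex)
    c = _reflected_gamma_cf(t, alpha, beta, P)
    w = stats.poisson.pmf(np.arange(kmax + 1), M)
    # Horner evaluation of the polynomial in c
    out = np.full_like(c, w[kmax])
    for k in range(kmax - 1, -1, -1):
        out = out * c + w[k]
    return out


class _FourierGrid:
    """Cached quadrature grid for CF inversion at fixed evaluation points."""

    def __init__(self, x, sigma_min: float, settings: LikelihoodSettings):
        x = np.atleast_1d(np.asarray(x, float))
        self.x = x
        period = 2.0 * max(float(np.max(np.abs(x))), 0.5) + settings.alias_allowance
        t_max = math.sqrt(-2.0 * math.log(1e-16)) / sigma_min
        dt = 2.0 * math.pi / period
        n = int(t_max / dt) + 2
        self.t = np.linspace(0.0, t_max, n)
        self.dt = self.t[1] - self.t[0]
        self.weights = np.full(n, self.dt)
        self.weights[0] = self.weights[-1] = 0.5 * self.dt
        # E[i, m] = exp(-i t_m x_i); densities follow by one matvec per call
        self.E = np.exp(-1j * np.outer(x, self.t))
        self.settings = settings

    def density(self, M, P, alpha, beta, sigma):
        kmax = k_truncation(M, self.settings.poisson_tail, self.settings.k_cap)
        phi = _mixture_cf(self.t, M, P, alpha, beta, kmax)
        phi = phi * np.exp(-0.5 * (sigma * self.t) ** 2) * self.weights
        f = (self.E @ phi).real / math.pi
        return np.maximum(f, DENSITY_FLOOR)


def line_density(z, params: MutationModelParams, settings: LikelihoodSettings | None = None):
    """Density of line means at ``z`` under the compound-Poisson model."""
    settings = settings or LikelihoodSettings()
    z = np.atleast_1d(np.asarray(z, float))
    sigma_min = max(params.sigma_env * 0.5, settings.sigma_floor_abs)
    grid = _FourierGrid(z - 1.0, sigma_min, settings)
    return grid.density(params.M, params.P, params.alpha, params.beta, params.sigma_env)


def line_loglik(z, params: MutationModelParams, settings: LikelihoodSettings | None = None):
    """Log density of line means; exactly Normal(1, sigma^2) when U = 0."""
    if params.U == 0:
        return stats.norm.logpdf(np.atleast_1d(np.asarray(z, float)), 1.0, params.sigma_env)
    return np.log(line_density(z, params, settings))


def effect_sum_density(k: int, j: int, alpha: float, beta: float, grid) -> np.ndarray:
    """Density, on ``grid``, of the summed effect of k mutations of which j
    are beneficial: X - Y with X ~ Gamma(j*beta, rate alpha), Y ~
    Gamma((k-j)*beta, rate alpha) and Gamma(0, .) a point mass at zero.

    ``grid`` must be a uniform, symmetric grid.  One-sided cases return the
    (possibly mirrored) gamma pdf; the two-sided case convolves cell masses
    (cdf increments), which integrates to 1 up to the truncated tail mass.
    """
    if k < 1 or not 0 <= j <= k:
        raise ValueError("need k >= 1 and 0 <= j <= k")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    grid = np.asarray(grid, float)
    ds = grid[1] - grid[0]
    pos = stats.gamma(a=j * beta, scale=1.0 / alpha)
    neg = stats.gamma(a=(k - j) * beta, scale=1.0 / alpha)
    if j == k or j == 0:
        dist, sign = (pos, 1.0) if j == k else (neg, -1.0)
        s = sign * grid
        d = np.where(s >= 0, dist.pdf(np.maximum(s, 0.0)), 0.0)
        # at the jump (or integrable singularity) at 0, represent the node by
        # its cell-averaged mass so the grid density integrates correctly
        zero = np.abs(grid) < 0.5 * ds
        d[zero] = dist.cdf(0.5 * ds) / ds
        return d
    edges = np.concatenate([grid - 0.5 * ds, [grid[-1] + 0.5 * ds]])
    mass_pos = np.diff(pos.cdf(np.clip(edges, 0.0, None)))
    mass_neg = np.diff(neg.cdf(np.clip(edges, 0.0, None)))
    n = len(grid)
    c = int(np.argmin(np.abs(grid)))  # index of the zero node
    full = np.convolve(mass_pos, mass_neg[::-1])  # offset s - (n-1)
    lo = (n - 1) - c
    return full[lo:lo + n] / ds


@dataclass(frozen=True)
class SupportInterval:
    """2-log-unit support interval with open-endedness flags."""

    lower: float
    upper: float
    open_lower: bool = False
    open_upper: bool = False

    def contains(self, x: float) -> bool:
        lo = -math.inf if self.open_lower else self.lower
        hi = math.inf if self.open_upper else self.upper
        return lo <= x <= hi or (self.lower <= x <= self.upper)


def support_interval(theta, loglik, drop: float = 2.0, log_scale: bool = False) -> SupportInterval:
    """Interval where the profile log-likelihood is within ``drop`` of its
    maximum, with endpoints interpolated between grid points; an endpoint at
    the edge of the searched grid is flagged open.
    """
    theta = np.asarray(theta, float)
    ll = np.asarray(loglik, float)
    ok = np.isfinite(ll)
    theta, ll = theta[ok], ll[ok]
    if len(theta) == 0:
        raise ValueError("profile has no finite values")
    order = np.argsort(theta)
    theta, ll = theta[order], ll[order]
    x = np.log(theta) if log_scale else theta
    best = int(np.argmax(ll))
    thresh = ll[best] - drop
    if np.ptp(ll) < 1e-9:
        warnings.warn("profile entirely flat: both interval ends open")
        return SupportInterval(theta[0], theta[-1], True, True)

    def cross(i0, i1):
        # linear interpolation of the threshold crossing between grid points
        x0, x1, y0, y1 = x[i0], x[i1], ll[i0], ll[i1]
        if y1 == y0:
            return x1
        w = (thresh - y0) / (y1 - y0)
        return x0 + w * (x1 - x0)

    # walk left from the maximum
    i = best
    while i > 0 and ll[i - 1] >= thresh:
        i -= 1
    if i == 0:
        lower, open_lower = x[0], ll[0] >= thresh
    else:
        lower, open_lower = cross(i, i - 1), False
    i = best
    while i < len(ll) - 1 and ll[i + 1] >= thresh:
        i += 1
    if i == len(ll) - 1:
        upper, open_upper = x[-1], ll[-1] >= thresh
    else:
        upper, open_upper = cross(i, i + 1), False
    if log_scale:
        lower, upper = math.exp(lower), math.exp(upper)
    return SupportInterval(float(lower), float(upper), bool(open_lower), bool(open_upper))


@dataclass
class MutationEffectsResults:
    """Fitted mutation-parameter estimates with profiles and intervals."""

    params_hat: MutationModelParams
    loglik: float
    profile: pd.DataFrame  # one row per (beta, P) cell
    support_intervals: dict  # name -> SupportInterval
    equal_effects: bool = False
    effect_size: float | None = None  # a-hat under the equal-effects model
    ridge: bool = False
    flat_surface: bool = False
    n_failed_cells: int = 0
    settings: LikelihoodSettings | None = None

    @property
    def U(self) -> float:
        return self.params_hat.U

    @property
    def mean_effect(self) -> float:
        return self.effect_size if self.equal_effects else self.params_hat.mean_effect

    def summary(self) -> str:
        model = "equal effects" if self.equal_effects else "reflected gamma"
        lines = [
            f"Mutation-effects ML fit ({model} model)",
            f"  log-likelihood: {self.loglik:.3f}",
            f"  U      = {self.U:.3g} /genome/generation "
            f"{_fmt_si(self.support_intervals.get('U'))}",
            f"  E(a)   = {self.mean_effect:.3g} {_fmt_si(self.support_intervals.get('E_a'))}",
            f"  P      = {self.params_hat.P:.2f} {_fmt_si(self.support_intervals.get('P'))}",
            f"  sigma  = {self.params_hat.sigma_env:.4f}",
        ]
        if not self.equal_effects:
            lines.append(f"  beta   = {self.params_hat.beta:.3g}, "
                         f"alpha = {self.params_hat.alpha:.3g}")
        if self.ridge:
            lines.append("  note: likelihood ridge detected (U upper bound open: "
                         "many tiny effects indistinguishable from fewer large ones)")
        if self.flat_surface:
            lines.append("  note: likelihood surface flat across the grid")
        return "\n".join(lines)


def _fmt_si(si: SupportInterval | None) -> str:
    if si is None:
        return ""
    lo = "0" if si.open_lower else f"{si.lower:.3g}"
    hi = "inf" if si.open_upper else f"{si.upper:.3g}"
    return f"({lo} - {hi})"


class MutationEffectsModel:
    """Compound-Poisson reflected-gamma model of MA line means.

    Parameters
    ----------
    ancestor : array
        Ancestor replicate values on the relative-fitness scale
        (mutation-free observations; they anchor sigma_env and must number
        at least 5).
    lines : array
        Per-line mean relative fitness of the MA lines (>= 10).
    G : int
        Cell generations of accumulation.
    equal_effects : bool
        Fit the equal-effects variant (single effect magnitude a) instead
        of the reflected gamma.
    """

    def __init__(self, ancestor, lines, G: int = 994,
                 equal_effects: bool = False,
                 settings: LikelihoodSettings | None = None):
        self.ancestor = np.asarray(ancestor, float)
        self.lines = np.asarray(lines, float)
        if len(self.ancestor) < 5:
            raise ValueError("need >= 5 ancestor replicates")
        if len(self.lines) < 10:
            raise ValueError("need >= 10 MA lines")
        self.G = G
        self.equal_effects = equal_effects
        self.settings = settings or LikelihoodSettings()
        anc_sd = float(np.std(self.ancestor, ddof=1))
        self.sigma_floor = max(anc_sd * self.settings.sigma_floor_factor,
                               self.settings.sigma_floor_abs)
        self._grid = _FourierGrid(self.lines - 1.0, self.sigma_floor, self.settings)
        self._log_sigma_bounds = (math.log(self.sigma_floor), math.log(max(4 * anc_sd, 0.2)))
        # U search ceiling: beyond M ~ 2/3 of the k cap the truncated Poisson
        # sum loses real mass and the likelihood is biased low; an interval
        # endpoint at this bound is therefore an *open* end (the flat-ridge
        # infinity), not a genuine crossing
        u_max = min(math.exp(LOG_U_BOUNDS[1]),
                    (2.0 * self.settings.k_cap / 3.0) / self.G)
        self._log_u_bounds = (LOG_U_BOUNDS[0], math.log(u_max))
        self._finite_profile = None

    # -- likelihood ---------------------------------------------------------

    def loglik(self, U, alpha, beta, P, sigma) -> float:
        """Joint log-likelihood of ancestor replicates and line means."""
        ll_anc = float(np.sum(stats.norm.logpdf(self.ancestor, 1.0, sigma)))
        M = U * self.G
        if M <= 0:
            f = stats.norm.pdf(self.lines, 1.0, sigma)
            return ll_anc + float(np.sum(np.log(np.maximum(f, DENSITY_FLOOR))))
        f = self._grid.density(M, P, alpha, beta, sigma)
        return ll_anc + float(np.sum(np.log(f)))

    def loglik_equal(self, U, a, P, sigma) -> float:
        """Equal-effects variant: offsets (2j - k) a with normal noise."""
        ll_anc = float(np.sum(stats.norm.logpdf(self.ancestor, 1.0, sigma)))
        M = U * self.G
        kmax = k_truncation(M, self.settings.poisson_tail, self.settings.k_cap)
        offsets = np.arange(-kmax, kmax + 1)
        wts = np.zeros(len(offsets))
        pois = stats.poisson.pmf(np.arange(kmax + 1), M)
        for k in range(kmax + 1):
            j = np.arange(k + 1)
            wts[(2 * j - k) + kmax] += pois[k] * stats.binom.pmf(j, k, P)
        means = 1.0 + offsets * a
        f = (wts[None, :] * stats.norm.pdf(self.lines[:, None], means[None, :], sigma)).sum(axis=1)
        return ll_anc + float(np.sum(np.log(np.maximum(f, DENSITY_FLOOR))))

    # -- optimization helpers ----------------------------------------------

    def _penalized(self, value, lo, hi):
        pen = 0.0
        if value < lo:
            pen = 1e4 * (lo - value) ** 2
            value = lo
        elif value > hi:
            pen = 1e4 * (value - hi) ** 2
            value = hi
        return value, pen

    def _cell_objective(self, beta, P):
        lu_lo, lu_hi = self._log_u_bounds
        la_lo, la_hi = LOG_ALPHA_BOUNDS
        ls_lo, ls_hi = self._log_sigma_bounds

        def nll(theta):
            lu, la, ls = theta
            lu, p1 = self._penalized(lu, lu_lo, lu_hi)
            la, p2 = self._penalized(la, la_lo, la_hi)
            ls, p3 = self._penalized(ls, ls_lo, ls_hi)
            ll = self.loglik(math.exp(lu), math.exp(la), beta, P, math.exp(ls))
            return -(ll) + p1 + p2 + p3

        return nll

    def _moment_start(self, beta, P):
        """Moment-matching start for (U, alpha) given (beta, P)."""
        anc_sd = max(float(np.std(self.ancestor, ddof=1)), self.sigma_floor)
        shift = 1.0 - float(np.mean(self.lines))
        v = max(float(np.var(self.lines, ddof=1)) - anc_sd ** 2, 1e-8)
        one_minus_2p = 1.0 - 2.0 * P
        if shift > 1e-4 and one_minus_2p > 0.05:
            alpha = (beta + 1.0) * shift * one_minus_2p / v
            alpha = min(max(alpha, 1e-2), 1e5)
            M = v * alpha ** 2 / (beta * (beta + 1.0))
        else:
            alpha = beta / 0.1
            M = v * alpha ** 2 / (beta * (beta + 1.0))
        M = min(max(M, 1e-3), 40.0)
        return M / self.G, alpha, anc_sd

    def _optimize_cell(self, beta, P, x0_list):
        nll = self._cell_objective(beta, P)
        best = None
        for x0 in x0_list[: self.settings.n_starts]:
            res = optimize.minimize(
                nll, x0, method="Nelder-Mead",
                options=dict(maxiter=self.settings.maxiter,
                             xatol=self.settings.xatol, fatol=self.settings.fatol))
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
        return best

    # -- fitting ------------------------------------------------------------

    def fit(self) -> MutationEffectsResults:
        if self.equal_effects:
            return self._fit_equal()
        s = self.settings
        cells = [(float(b), float(P)) for b in s.beta_grid for P in s.P_grid]
        rows, n_failed = [], 0
        results_by_cell = {}
        for beta, P in cells:
            self._run_cell(beta, P, rows, results_by_cell)
        n_failed = sum(1 for r in rows if not np.isfinite(r["loglik"]))

        for _ in range(s.refine_rounds):
            best = max((r for r in rows if np.isfinite(r["loglik"])),
                       key=lambda r: r["loglik"])
            new_cells = self._refined_cells(best["beta"], best["P"], rows)
            for beta, P in new_cells:
                if (beta, P) not in results_by_cell:
                    self._run_cell(beta, P, rows, results_by_cell)

        profile = pd.DataFrame(rows)
        finite = profile[np.isfinite(profile["loglik"])]
        if finite.empty:
            raise RuntimeError("likelihood optimization failed in every cell")
        best_row = finite.loc[finite["loglik"].idxmax()]
        flat = float(finite["loglik"].max() - finite["loglik"].min()) < s.support_drop
        self._finite_profile = finite

        params_hat = MutationModelParams(
            U=best_row["U"], alpha=best_row["alpha"], beta=best_row["beta"],
            sigma_env=best_row["sigma"], P=best_row["P"], G=self.G)
        intervals = self._support_intervals(params_hat, finite)
        ridge = intervals["U"].open_upper
        return MutationEffectsResults(
            params_hat=params_hat, loglik=float(best_row["loglik"]),
            profile=profile, support_intervals=intervals,
            equal_effects=False, ridge=ridge, flat_surface=flat,
            n_failed_cells=n_failed, settings=s)

    def _run_cell(self, beta, P, rows, results_by_cell):
        U0, alpha0, sigma0 = self._moment_start(beta, P)
        base = [math.log(U0), math.log(alpha0), math.log(sigma0)]
        starts = [
            base,
            [base[0] + math.log(5.0), base[1] + math.log(5.0), base[2]],
            [base[0] - math.log(5.0), base[1] - math.log(5.0), base[2]],
        ]
        res = self._optimize_cell(beta, P, starts)
        if res is None:
            warnings.warn(f"cell (beta={beta}, P={P}) failed to converge; excluded")
            rows.append(dict(beta=beta, P=P, U=np.nan, alpha=np.nan,
                             sigma=np.nan, loglik=np.nan))
            return
        lu, la, ls = res.x
        lu = min(max(lu, self._log_u_bounds[0]), self._log_u_bounds[1])
        la = min(max(la, LOG_ALPHA_BOUNDS[0]), LOG_ALPHA_BOUNDS[1])
        ls = min(max(ls, self._log_sigma_bounds[0]), self._log_sigma_bounds[1])
        row = dict(beta=beta, P=P, U=math.exp(lu), alpha=math.exp(la),
                   sigma=math.exp(ls), loglik=-float(res.fun))
        rows.append(row)
        results_by_cell[(beta, P)] = row

    def _refined_cells(self, beta_best, P_best, rows):
        """Midpoint refinement around the best cell; P may exceed 0.5."""
        betas = sorted({r["beta"] for r in rows})
        Ps = sorted({r["P"] for r in rows})
        new = []
        bi = betas.index(beta_best)
        for nb in (bi - 1, bi + 1):
            if 0 <= nb < len(betas):
                new_beta = math.sqrt(beta_best * betas[nb])
                new.append((round(new_beta, 6), P_best))
        pi = Ps.index(P_best)
        for npi in (pi - 1, pi + 1):
            if 0 <= npi < len(Ps):
                new.append((beta_best, round(0.5 * (P_best + Ps[npi]), 6)))
        if pi == len(Ps) - 1 and P_best >= 0.5 - 1e-9:
            new.append((beta_best, min(round(P_best + 0.1, 6), 0.95)))
        return new

    # -- profiles and intervals ---------------------------------------------

    def _profile_cells(self, params_hat):
        """(beta, P) cells over which profiles are enveloped: the best cell
        plus any cell within 2 log units of it (the grid-profile reading of
        the support interval — the fixed-shape conditional profile alone
        understates the uncertainty)."""
        if self._finite_profile is None:
            return [(params_hat.beta, params_hat.P)]
        prof = self._finite_profile
        best = prof["loglik"].max()
        keep = prof[prof["loglik"] >= best - self.settings.support_drop]
        keep = keep.sort_values("loglik", ascending=False).head(4)
        cells = [(float(r.beta), float(r.P)) for r in keep.itertuples()]
        hat = (params_hat.beta, params_hat.P)
        if hat not in cells:
            cells.insert(0, hat)
        return cells

    def _profile_1d(self, fixed_name, grid_values, params_hat):
        """Profile log-likelihood over one parameter: at each grid value the
        two free nuisance parameters are re-maximized (warm-started from the
        neighboring value) within every candidate (beta, P) cell, and the
        cell envelope is taken."""
        cells = self._profile_cells(params_hat)

        def make_nll(v, beta, P):
            if fixed_name == "U":
                def nll(theta, v=v):
                    la, p2 = self._penalized(theta[0], *LOG_ALPHA_BOUNDS)
                    ls, p3 = self._penalized(theta[1], *self._log_sigma_bounds)
                    return -self.loglik(v, math.exp(la), beta, P, math.exp(ls)) + p2 + p3
            else:  # E(a): alpha = beta / E(a), profile over (U, sigma)
                alpha_v = beta / v
                def nll(theta, alpha_v=alpha_v):
                    lu, p1 = self._penalized(theta[0], *self._log_u_bounds)
                    ls, p3 = self._penalized(theta[1], *self._log_sigma_bounds)
                    return -self.loglik(math.exp(lu), alpha_v, beta, P, math.exp(ls)) + p1 + p3
            return nll

        if fixed_name == "U":
            center_x0 = [math.log(params_hat.alpha), math.log(params_hat.sigma_env)]
            center_val = params_hat.U
        else:
            center_x0 = [math.log(params_hat.U), math.log(params_hat.sigma_env)]
            center_val = params_hat.mean_effect

        # walk outward from the point estimate so each nuisance optimization
        # warm-starts from its neighbor (profiles are smooth in the fixed
        # parameter; starting at a search bound would strand the optimizer)
        grid_values = np.asarray(grid_values, float)
        lls = np.full(len(grid_values), np.nan)
        for beta, P in cells:
            x0 = list(center_x0)
            if fixed_name == "U":
                # keep the starting E(a) of the hat, rescaled to this beta
                x0[0] = math.log(beta / params_hat.mean_effect)
            i_center = int(np.argmin(np.abs(np.log(grid_values)
                                            - math.log(center_val))))
            for direction in (range(i_center, len(grid_values)),
                              range(i_center - 1, -1, -1)):
                warm = list(x0)
                for i in direction:
                    res = optimize.minimize(
                        make_nll(grid_values[i], beta, P), warm,
                        method="Nelder-Mead",
                        options=dict(maxiter=120, xatol=2e-3, fatol=5e-4))
                    if np.isfinite(res.fun):
                        warm = list(res.x)
                        lls[i] = np.nanmax([lls[i], -float(res.fun)])
        return lls

    def _centered_log_grid(self, center, span, n, lo, hi):
        g = np.geomspace(max(center / 10 ** span, lo), min(center * 10 ** span, hi), n)
        return np.unique(np.concatenate([[lo], g, [hi], [center]]))

    def _profiled_interval(self, fixed_name, grid, params_hat):
        """Coarse profile, then bisection of the 2-log-unit crossings with
        the nuisance parameters re-maximized at every probe."""
        s = self.settings
        lls = self._profile_1d(fixed_name, grid, params_hat)
        ok = np.isfinite(lls)
        grid, lls = np.asarray(grid)[ok], lls[ok]
        if len(grid) == 0:
            raise RuntimeError(f"profile for {fixed_name} failed everywhere")
        best = int(np.argmax(lls))
        thresh = lls[best] - s.support_drop
        if np.ptp(lls) < 1e-9:
            warnings.warn("profile entirely flat: both interval ends open")
            return SupportInterval(float(grid[0]), float(grid[-1]), True, True)

        def bisect(v_in, v_out, ll_in):
            for _ in range(7):
                mid = math.sqrt(v_in * v_out)
                ll_mid = self._profile_1d(fixed_name, [mid], params_hat)[0]
                if not np.isfinite(ll_mid) or ll_mid < thresh:
                    v_out = mid
                else:
                    v_in = mid
            return v_in

        # lower side
        i = best
        while i > 0 and lls[i - 1] >= thresh:
            i -= 1
        if i == 0:
            lower, open_lower = float(grid[0]), bool(lls[0] >= thresh)
        else:
            lower, open_lower = bisect(grid[i], grid[i - 1], lls[i]), False
        # upper side
        i = best
        while i < len(lls) - 1 and lls[i + 1] >= thresh:
            i += 1
        if i == len(lls) - 1:
            upper, open_upper = float(grid[-1]), bool(lls[-1] >= thresh)
        else:
            upper, open_upper = bisect(grid[i], grid[i + 1], lls[i]), False
        return SupportInterval(float(lower), float(upper), open_lower, open_upper)

    def _support_intervals(self, params_hat, finite_profile):
        s = self.settings
        out = {}
        u_grid = self._centered_log_grid(
            params_hat.U, s.profile_span_decades, s.profile_points,
            math.exp(self._log_u_bounds[0]), math.exp(self._log_u_bounds[1]))
        out["U"] = self._profiled_interval("U", u_grid, params_hat)
        # E(a) profile at the best beta (alpha re-parameterized)
        ea_grid = self._centered_log_grid(
            params_hat.mean_effect, s.profile_span_decades, s.profile_points,
            1e-6, 2.0)
        out["E_a"] = self._profiled_interval("E_a", ea_grid, params_hat)
        # P from the per-P envelope of the cell grid
        envelope = finite_profile.groupby("P")["loglik"].max()
        if len(envelope) >= 2:
            si = support_interval(envelope.index.to_numpy(), envelope.to_numpy(),
                                  s.support_drop)
            # P = 0 is a genuine boundary of the parameter, not a search limit
            if si.lower <= min(envelope.index) + 1e-12 and si.open_lower:
                si = replace(si, lower=float(min(envelope.index)), open_lower=False)
            out["P"] = si
        return out

    # -- equal-effects variant ----------------------------------------------

    def _fit_equal(self) -> MutationEffectsResults:
        s = self.settings
        rows = []
        anc_sd = max(float(np.std(self.ancestor, ddof=1)), self.sigma_floor)
        shift = max(1.0 - float(np.mean(self.lines)), 1e-3)
        v = max(float(np.var(self.lines, ddof=1)) - anc_sd ** 2, 1e-8)
        for P in s.P_grid:
            one_minus_2p = max(1.0 - 2.0 * P, 0.05)
            a0 = max(v / shift / one_minus_2p, 1e-3)
            M0 = min(max(shift / (a0 * one_minus_2p), 1e-3), 40.0)

            def nll(theta, P=P):
                lu, p1 = self._penalized(theta[0], *self._log_u_bounds)
                la_, p2 = self._penalized(theta[1], math.log(1e-6), math.log(2.0))
                ls, p3 = self._penalized(theta[2], *self._log_sigma_bounds)
                return -self.loglik_equal(math.exp(lu), math.exp(la_), P,
                                          math.exp(ls)) + p1 + p2 + p3

            base = [math.log(M0 / self.G), math.log(a0), math.log(anc_sd)]
            starts = [base,
                      [base[0] + math.log(5.0), base[1] - math.log(5.0), base[2]],
                      [base[0] - math.log(5.0), base[1] + math.log(5.0), base[2]]]
            best = None
            for x0 in starts[: s.n_starts]:
                res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                        options=dict(maxiter=s.maxiter,
                                                     xatol=s.xatol, fatol=s.fatol))
                if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                    best = res
            if best is None:
                rows.append(dict(beta=np.nan, P=P, U=np.nan, alpha=np.nan,
                                 sigma=np.nan, a=np.nan, loglik=np.nan))
                continue
            lu, la_, ls = best.x
            rows.append(dict(
                beta=np.nan, P=float(P),
                U=math.exp(min(max(lu, self._log_u_bounds[0]), self._log_u_bounds[1])),
                a=math.exp(la_), alpha=1.0 / math.exp(la_),
                sigma=math.exp(ls), loglik=-float(best.fun)))
        profile = pd.DataFrame(rows)
        finite = profile[np.isfinite(profile["loglik"])]
        if finite.empty:
            raise RuntimeError("equal-effects optimization failed for every P")
        best_row = finite.loc[finite["loglik"].idxmax()]
        a_hat = float(best_row["a"])
        params_hat = MutationModelParams(
            U=float(best_row["U"]), alpha=1.0 / a_hat, beta=1.0,
            sigma_env=float(best_row["sigma"]), P=float(best_row["P"]), G=self.G)
        envelope = finite.groupby("P")["loglik"].max()
        intervals = {}
        if len(envelope) >= 2:
            intervals["P"] = support_interval(envelope.index.to_numpy(),
                                              envelope.to_numpy(), self.settings.support_drop)
        return MutationEffectsResults(
            params_hat=params_hat, loglik=float(best_row["loglik"]),
            profile=profile, support_intervals=intervals,
            equal_effects=True, effect_size=a_hat,
            flat_surface=float(finite["loglik"].max() - finite["loglik"].min())
            < self.settings.support_drop,
            settings=self.settings)


def fit_ml(ancestor, lines, G: int = 994,
           settings: LikelihoodSettings | None = None) -> MutationEffectsResults:
    """Fit the reflected-gamma compound-Poisson model."""
    return MutationEffectsModel(ancestor, lines, G=G, settings=settings).fit()


def fit_equal_effects(ancestor, lines, G: int = 994, P_grid=None,
                      settings: LikelihoodSettings | None = None) -> MutationEffectsResults:
    """Fit the equal-effects variant (single effect magnitude)."""
    settings = settings or LikelihoodSettings()
    if P_grid is not None:
        settings = replace(settings, P_grid=tuple(P_grid))
    return MutationEffectsModel(ancestor, lines, G=G, equal_effects=True,
                                settings=settings).fit()
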