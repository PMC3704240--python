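"""Nonparametric group comparisons, outlier screening, and per-line
significance calls.

The analysis is rank-based by design: Wilcoxon rank-sum tests for group
means, a median-centered rank Levene test for group variances, and
Kruskal-Wallis tests for block effects among ancestor replicates.  Per-line
calls compare each MA line's mean to a normal confidence band around the
ancestor mean, Bonferroni-corrected over the family of tested lines.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import FitnessTable, summarize

#: Combined sample size at or below which the rank-sum test enumerates all
#: splits exactly (midranks, so ties are handled).
EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple = ()
    adjusted_p: float | None = None
    df: float | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class SignificanceCall:
    """Per-line classification against the ancestor confidence band."""

    line_id: str
    trait: str
    direction: str  # "low", "none", "high"
    z_score: float  # (line mean - ancestor mean) / ancestor SD
    cutoff: float


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of equal location.

    Midranks handle ties.  For combined n <= 20 the null distribution of the
    rank sum is enumerated over all splits (exact even with ties); larger
    samples use the tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult("wilcoxon_rank_sum", 0.0, 1.0, ("a", "b"), degenerate=True)
    if len(pooled) <= EXACT_WILCOXON_MAX_N:
        ranks = stats.rankdata(pooled)
        n_a = len(a)
        w_obs = ranks[:n_a].sum()
        mu = n_a * (len(pooled) + 1) / 2.0
        dev_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), n_a):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mu) >= dev_obs - 1e-12:
                count += 1
        return TestResult("wilcoxon_rank_sum", float(w_obs), count / total, ("a", "b"))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), ("a", "b"))


def rank_levene(groups: dict | list) -> TestResult:
    """Median-centered rank Levene test of equal spread.

    Each group's median is subtracted, all data are pooled and converted to
    midranks, and a classical Levene test (one-way analysis of absolute
    deviations of the ranks from their group means) is run on the ranked
    values in their original groupings.
    """
    if isinstance(groups, dict):
        labels, arrays = zip(*sorted(groups.items()))
    else:
        labels = tuple(range(len(groups)))
        arrays = tuple(np.asarray(g, float) for g in groups)
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs >= 2 values")
    centered = [np.asarray(g, float) - np.median(g) for g in arrays]
    pooled = np.concatenate(centered)
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for g in centered:
        out.append(ranks[start:start + len(g)])
        start += len(g)
    if all(np.ptp(r) == 0 for r in out):
        return TestResult("rank_levene", 0.0, 1.0, labels, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.levene(*out, center="mean")
    if math.isnan(stat):
        return TestResult("rank_levene", 0.0, 1.0, labels, degenerate=True)
    return TestResult("rank_levene", float(stat), float(p), labels)


def kruskal_wallis_blocks(values_by_block: dict) -> TestResult:
    """Kruskal-Wallis test for block effects (tie-corrected), df = blocks - 1."""
    blocks = sorted(values_by_block)
    if len(blocks) < 2:
        raise ValueError("need >= 2 blocks")
    arrays = [np.asarray(values_by_block[b], float) for b in blocks]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0, tuple(blocks),
                          df=len(blocks) - 1, degenerate=True)
    stat, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p),
                      tuple(blocks), df=len(blocks) - 1)


def screen_outliers(values, k: float = 4.0):
    """Flag values more than k SDs from the mean (single pass; mean and SD
    include the candidate).

    Returns
    -------
    (retained, flags) : (ndarray, boolean ndarray)
        flags[i] True marks an outlier; retained drops flagged values.
    """
    vals = np.asarray(values, float)
    if len(vals) < 3:
        raise ValueError("need >= 3 values to screen outliers")
    mean = vals.mean()
    sd = vals.std(ddof=1)
    dev = np.abs(vals - mean)
    if sd == 0:
        flags = dev > 0  # discordant value against zero spread: infinite z
    else:
        flags = dev > k * sd
    return vals[~flags], flags


def bonferroni_cutoff(alpha: float, family_size: int) -> float:
    """Two-sided standard-normal quantile z with 2*(1 - Phi(z)) = alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return float(stats.norm.isf(alpha / (2.0 * family_size)))


def classify_lines(
    table: FitnessTable,
    trait: str,
    cutoff: float | None = None,
    alpha: float = 0.05,
    family_size: int | None = None,
    group: str = "MA",
):
    """Classify each line's mean against the ancestor confidence band.

    Bounds are ancestor_mean +/- cutoff * ancestor_SD on the relative scale.
    When ``cutoff`` is not given it is derived from ``alpha`` Bonferroni-
    corrected over ``family_size`` (default: all tested lines, MA + control).

    Returns
    -------
    (calls, bounds) : (list of SignificanceCall, (lower, upper))
    """
    summaries = summarize(table, trait)
    if "ancestor" not in summaries:
        raise ValueError(f"no ancestor replicates for {trait!r}")
    anc = summaries["ancestor"]
    if anc.variance is None:
        raise ValueError("ancestor variance undefined (single replicate)")
    if cutoff is None:
        if family_size is None:
            family_size = table.n_ma + table.n_control
        cutoff = bonferroni_cutoff(alpha, family_size)
    sd = anc.sd
    if sd == 0:
        warnings.warn(
            f"ancestor SD is zero for {trait!r}: bounds degenerate, every "
            "deviating line flagged")
    bounds = (anc.mean - cutoff * sd, anc.mean + cutoff * sd)
    calls = []
    for line_id, value in table.line_means(trait, group).items():
        if sd == 0:
            z = 0.0 if value == anc.mean else math.copysign(math.inf, value - anc.mean)
        else:
            z = (value - anc.mean) / sd
        if z < -cutoff:
            direction = "low"
        elif z > cutoff:
            direction = "high"
        else:
            direction = "none"
        calls.append(SignificanceCall(line_id=line_id, trait=trait,
                                      direction=direction, z_score=float(z),
                                      cutoff=float(cutoff)))
    return calls, bounds


def count_calls(calls) -> tuple[int, int]:
    """(low, high) counts from a list of SignificanceCall."""
    low = sum(1 for c in calls if c.direction == "low")
    high = sum(1 for c in calls if c.direction == "high")
    return low, high


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-comparison adjustment (monotone, clipped at 1)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if len(p) == 0:
        return p.copy()
    name = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}.get(method)
    if name is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=name)[1]


def shapiro_wilk(values) -> TestResult:
    """Descriptive normality screen (gates nothing downstream)."""
    stat, p = stats.shapiro(np.asarray(values, float))
    return TestResult("shapiro_wilk", float(stat), float(p))


def trait_comparison_battery(table: FitnessTable, trait: str) -> dict[str, TestResult]:
    """The per-trait test battery behind the group-summary table: Wilcoxon
    mean comparisons (control vs ancestor, MA vs ancestor, MA vs control) and
    the three-group rank Levene variance comparisons (pairwise)."""
    anc = table.ancestor_values(trait)
    ctrl = table.line_means(trait, "control").to_numpy(float)
    ma = table.line_means(trait, "MA").to_numpy(float)
    out = {}
    pairs = {
        "mean_control_vs_ancestor": (ctrl, anc),
        "mean_ma_vs_ancestor": (ma, anc),
        "mean_ma_vs_control": (ma, ctrl),
    }
    for name, (x, y) in pairs.items():
        if len(x) >= 2 and len(y) >= 2:
            out[name] = wilcoxon_rank_sum(x, y)
    var_pairs = {
        "var_control_vs_ancestor": (ctrl, anc),
        "var_ma_vs_ancestor": (ma, anc),
        "var_ma_vs_control": (ma, ctrl),
    }
    for name, (x, y) in var_pairs.items():
        if len(x) >= 2 and len(y) >= 2:
            out[name] = rank_levene([x, y])
    return out
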