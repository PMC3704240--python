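"""Published summary statistics of the original 90-line *Dictyostelium
discoideum* mutation-accumulation experiment.

The replicate-level trait measurements of that experiment were never
deposited; what is published are group summary tables (means and variances
of the ancestor, control, and MA distributions on the relative-fitness
scale), per-line significance counts, the pairwise Spearman correlation
matrix among the eight fitness components, the distribution of per-line
affected-component counts, and maximum-likelihood support bounds.  Those
summaries are sufficient inputs for the closed-form estimators and the
pleiotropy analyses in this package, and are collected here as module-level
constants for reanalysis and for the reproduction scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import TRAITS

#: Cell generations of mutation accumulation (70 single-cell bottlenecks
#: at 14.2 cell generations per transfer).
G = 994

N_MA_LINES = 90
N_CONTROL_LINES = 10

#: Group summaries per fitness component on the relative-fitness scale:
#: (ancestor mean, ancestor variance, ancestor n, MA mean, MA variance).
#: MA means/variances are over the 90 line means.
GROUP_SUMMARIES = {
    "plate_growth": dict(anc_mean=1.000, anc_var=0.0015, anc_n=16,
                         ma_mean=1.000, ma_var=0.0025),
    "liquid_growth": dict(anc_mean=1.000, anc_var=0.0011, anc_n=16,
                          ma_mean=0.705, ma_var=0.0471),
    "slug_distance": dict(anc_mean=1.000, anc_var=0.0017, anc_n=12,
                          ma_mean=0.889, ma_var=0.0245),
    "total_fbs": dict(anc_mean=1.000, anc_var=0.0014, anc_n=9,
                      ma_mean=0.969, ma_var=0.0112),
    "spores_per_fb": dict(anc_mean=1.000, anc_var=0.0017, anc_n=12,
                          ma_mean=0.919, ma_var=0.0290),
    "total_spores": dict(anc_mean=1.000, anc_var=0.0010, anc_n=12,
                         ma_mean=0.869, ma_var=0.0080),
    "spore_germination": dict(anc_mean=1.000, anc_var=0.0000, anc_n=17,
                              ma_mean=0.519, ma_var=0.0715),
    "competitive_ability": dict(anc_mean=0.999, anc_var=0.0007, anc_n=42,
                                ma_mean=0.900, ma_var=0.1247),
}

#: Published per-line 95% confidence bounds (Bonferroni-corrected) and the
#: number of MA lines (of 90) falling below/above them.
LINE_CALLS = {
    "plate_growth": dict(lower=0.867, upper=1.133, low=2, high=0),
    "liquid_growth": dict(lower=0.886, upper=1.114, low=67, high=1),
    "slug_distance": dict(lower=0.858, upper=1.142, low=42, high=6),
    "total_fbs": dict(lower=0.871, upper=1.129, low=14, high=3),
    "spores_per_fb": dict(lower=0.858, upper=1.142, low=35, high=8),
    "total_spores": dict(lower=0.968, upper=1.032, low=76, high=1),
    "spore_germination": dict(lower=0.993, upper=1.007, low=85, high=0),
    "competitive_ability": dict(lower=0.911, upper=1.089, low=44, high=17),
}


def significant_counts() -> np.ndarray:
    """Per-trait counts of significantly altered lines (low + high), in
    canonical trait order."""
    return np.array([LINE_CALLS[t]["low"] + LINE_CALLS[t]["high"]
                     for t in TRAITS])


#: Ancestor spore-germination replicate values after outlier screening:
#: fifteen plates at 100% germination and two at 99%.
GERMINATION_ANCESTOR_REPLICATES = [1.00] * 15 + [0.99] * 2

# upper triangle of the published pairwise Spearman correlations among the
# eight fitness components, in canonical trait order
_SPEARMAN_UPPER = [
    # plate vs (liquid, slug, fbs, spores/fb, total spores, germ, comp)
    [-0.03, -0.13, 0.22, -0.08, 0.06, -0.07, 0.00],
    [-0.06, -0.11, -0.04, -0.16, 0.04, -0.09],
    [0.17, -0.40, -0.26, 0.11, -0.04],
    [-0.25, 0.37, -0.02, -0.05],
    [0.62, -0.15, 0.02],
    [-0.23, -0.08],
    [0.08],
]


def spearman_correlation_matrix() -> pd.DataFrame:
    """The published 8x8 Spearman correlation matrix (unit diagonal)."""
    n = len(TRAITS)
    C = np.eye(n)
    for i, row in enumerate(_SPEARMAN_UPPER):
        for k, r in enumerate(row):
            j = i + 1 + k
            C[i, j] = C[j, i] = r
    return pd.DataFrame(C, index=list(TRAITS), columns=list(TRAITS))


#: Observed number of MA lines exhibiting 0-8 significantly altered fitness
#: components, and the published simulation expectation under independence.
AFFECTED_COMPONENT_COUNTS = dict(
    observed=np.array([0, 1, 4, 13, 24, 34, 11, 3, 0]),
    expected=np.array([0.01, 0.31, 3.23, 13.59, 28.33, 29.12, 13.38, 2.00, 0.04]),
)

#: Lower ends of the published 2-log-unit support intervals for the
#: per-component mutation rate U (ML fits; spore germination was abandoned
#: as a poor fit, so seven components carry a bound).
ML_U_LOWER_BOUNDS = {
    "plate_growth": 0.00003,
    "liquid_growth": 0.0024,
    "slug_distance": 0.0050,
    "total_fbs": 0.0012,
    "spores_per_fb": 0.0019,
    "total_spores": 0.0014,
    "competitive_ability": 0.0014,
}
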