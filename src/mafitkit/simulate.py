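"""Synthetic mutation-accumulation experiments.

Generates replicate-level fitness tables with the statistical structure the
downstream analysis assumes: per line and trait the number of accumulated
mutations is Poisson(U*G); each mutation's effect is drawn from a gamma
distribution with shape beta and rate alpha, reflected around zero — positive
with probability P, negative otherwise; a line's true relative fitness is
1 + sum(effects) (additive default; a multiplicative variant is available);
each replicate adds Normal(0, sigma_env) assay error.  Spore germination and
competitive ability are generated as binomial counts and converted to
proportions/indices, so downstream code sees the same schema as real data.

Control lines, which were propagated at larger population size so selection
could purge mutations, are modeled phenomenologically with a retention
factor kappa scaling their effective mutational input (U*kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .competition import CompetitionAssay, aggregate_reciprocal, competition_index
from .data import TRAITS, FitnessTable

#: Default generations of mutation accumulation (70 single-cell bottlenecks
#: at 14.2 cell generations per transfer).
DEFAULT_G = 994

#: Ancestor replicate counts per trait, matching the study design.
DEFAULT_ANCESTOR_REPS = {
    "plate_growth": 16,
    "liquid_growth": 16,
    "slug_distance": 12,
    "total_fbs": 9,
    "spores_per_fb": 12,
    "total_spores": 12,
    "spore_germination": 17,
    "competitive_ability": 42,
}

#: Replicates per MA/control line, following the assay protocol (five plaques
#: for plate growth, two 100-spore germination plates, two reciprocal
#: competition mixes averaged into paired replicates, one measure otherwise).
DEFAULT_REPS_PER_LINE = {
    "plate_growth": 5,
    "liquid_growth": 1,
    "slug_distance": 1,
    "total_fbs": 1,
    "spores_per_fb": 1,
    "total_spores": 1,
    "spore_germination": 2,
    "competitive_ability": 1,
}

#: Assay-error SDs on the relative-fitness scale, calibrated to the observed
#: ancestor replicate variances per trait.
DEFAULT_SIGMA_ENV = {
    "plate_growth": math.sqrt(0.0015),
    "liquid_growth": math.sqrt(0.0011),
    "slug_distance": math.sqrt(0.0017),
    "total_fbs": math.sqrt(0.0014),
    "spores_per_fb": math.sqrt(0.0017),
    "total_spores": math.sqrt(0.0010),
    "spore_germination": 0.0033,
    "competitive_ability": math.sqrt(0.0007),
}

#: Baseline (ancestral) spore germination rate.
ANCESTRAL_GERMINATION_RATE = 0.999


@dataclass(frozen=True)
class MutationModelParams:
    """Generative/inferential parameter bundle for one trait.

    U : fitness-altering mutations per haploid genome per cell generation
    G : cell generations of accumulation
    P : fraction of mutations with beneficial (positive) effect
    alpha : gamma rate parameter of the effect-magnitude distribution
    beta : gamma shape parameter; E(a) = beta/alpha
    sigma_env : assay-error SD on the relative-fitness scale
    """

    U: float
    alpha: float
    beta: float
    sigma_env: float
    P: float = 0.0
    G: int = DEFAULT_G

    def __post_init__(self):
        for name in ("U", "alpha", "beta", "sigma_env", "P"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.U < 0:
            raise ValueError("U must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if not 0 <= self.P <= 1:
            raise ValueError("P must be in [0, 1]")
        if self.sigma_env < 0:
            raise ValueError("sigma_env must be >= 0")

    @property
    def M(self) -> float:
        """Expected mutations per line, U*G."""
        return self.U * self.G

    @property
    def mean_effect(self) -> float:
        """E(a) = beta/alpha, the mean absolute fitness effect."""
        return self.beta / self.alpha


def params_for_mean_effect(U, mean_effect, beta=1.0, P=0.0, sigma_env=0.03, G=DEFAULT_G):
    """Build params from (U, E(a), beta) with alpha = beta/E(a)."""
    return MutationModelParams(
        U=U, alpha=beta / mean_effect, beta=beta, sigma_env=sigma_env, P=P, G=G
    )


def default_params(G: int = DEFAULT_G) -> dict[str, MutationModelParams]:
    """Study-condition parameter sets per trait.

    U and E(a) follow the per-trait mutational estimates where the data
    identified them (roughly U ~ 1e-4..4e-3, E(a) ~ 0.05..0.23, P ~ 0..0.4);
    sigma_env is calibrated to the observed ancestor variances.
    """
    spec = {
        # trait: (U, E(a), beta, P)
        "plate_growth": (0.0001, 0.112, 1.0, 0.3),
        "liquid_growth": (0.0039, 0.11, 1.0, 0.15),
        "slug_distance": (0.0050, 0.05, 1.0, 0.3),
        "total_fbs": (0.0027, 0.055, 1.0, 0.4),
        "spores_per_fb": (0.0019, 0.05, 1.0, 0.4),
        "total_spores": (0.0026, 0.052, 1.0, 0.0),
        "spore_germination": (0.0033, 0.148, 1.0, 0.0),
        "competitive_ability": (0.0015, 0.23, 1.0, 0.3),
    }
    return {
        t: params_for_mean_effect(
            U=u, mean_effect=ea, beta=b, P=p, sigma_env=DEFAULT_SIGMA_ENV[t], G=G
        )
        for t, (u, ea, b, p) in spec.items()
    }


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: line counts, replicate structure, control model."""

    n_ma: int = 90
    n_control: int = 10
    ancestor_reps: dict = field(default_factory=lambda: dict(DEFAULT_ANCESTOR_REPS))
    reps_per_line: dict = field(default_factory=lambda: dict(DEFAULT_REPS_PER_LINE))
    control_retention: float = 0.2  # kappa: effective mutational input of controls
    germination_spores_per_plate: int = 100
    competition_cells_scored: int = 500
    competition_spores_scored: int = 500
    seed: int | None = None

    def __post_init__(self):
        if self.n_ma < 1 or self.n_control < 0:
            raise ValueError("line counts must be positive")
        if not 0 <= self.control_retention <= 1:
            raise ValueError("control_retention must be in [0, 1]")
        for d in (self.ancestor_reps, self.reps_per_line):
            if any(v < 1 for v in d.values()):
                raise ValueError("replicate counts must be >= 1")


# -- core draws -------------------------------------------------------------


def draw_line_effects(params: MutationModelParams, n_lines: int, rng: np.random.Generator):
    """Vectorized compound-Poisson draw of per-line mutation counts and
    summed effects.

    Returns
    -------
    counts : int array (n_lines,)
    sums : float array (n_lines,) — sum of signed effects per line
    effects : list of per-line effect arrays
    """
    counts = rng.poisson(params.M, size=n_lines)
    total = int(counts.sum())
    if total == 0:
        return counts, np.zeros(n_lines), [np.array([])] * n_lines
    mags = rng.gamma(shape=params.beta, scale=1.0 / params.alpha, size=total)
    signs = np.where(rng.random(total) < params.P, 1.0, -1.0)
    effects_flat = signs * mags
    owner = np.repeat(np.arange(n_lines), counts)
    sums = np.bincount(owner, weights=effects_flat, minlength=n_lines)
    splits = np.cumsum(counts)[:-1]
    effects = np.split(effects_flat, splits)
    return counts, sums, effects


def true_line_value(sums, effects, multiplicative: bool = False):
    """Line true relative fitness from summed effects (1 + sum by default,
    or the product of (1 + a) under the multiplicative variant)."""
    if not multiplicative:
        return 1.0 + np.asarray(sums, float)
    return np.array([float(np.prod(1.0 + e)) for e in effects])


def simulate_germination_counts(
    line_true_rate: float,
    plates: int = 2,
    spores_per_plate: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binomial germinated-spore counts for one line (one draw per plate)."""
    if not 0.0 <= line_true_rate <= 1.0:
        raise ValueError(f"germination rate must be in [0, 1], got {line_true_rate}")
    if plates < 1 or spores_per_plate < 1:
        raise ValueError("plates and spores_per_plate must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    return rng.binomial(spores_per_plate, line_true_rate, size=plates)


def simulate_competition_counts(
    true_index: float,
    n_scored_cells: int = 500,
    n_scored_spores: int = 500,
    retention: float | None = None,
    rng: np.random.Generator | None = None,
    line_id: str = "line",
) -> list[CompetitionAssay]:
    """Both reciprocal competition mixes for one line.

    The initial labeled-cell fraction is Binomial around 0.5 (nominally equal
    mixes); the labeled-spore fraction is Binomial around the fraction implied
    by the competitive index: with initial line fraction f, the line's spore
    fraction is C*f / (C*f + (1-f)).  With ``retention`` set, that fraction of
    labeled spores keeps the dye and the remainder are scored as unlabeled.
    """
    if true_index <= 0:
        raise ValueError("true_index must be > 0")
    if n_scored_cells < 1 or n_scored_spores < 1:
        raise ValueError("scored counts must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    ret = 1.0 if retention is None else retention
    assays = []
    for labeled in ("line", "ancestor"):
        n_labeled_cells = int(rng.binomial(n_scored_cells, 0.5))
        n_labeled_cells = min(max(n_labeled_cells, 1), n_scored_cells - 1)
        f_lab = n_labeled_cells / n_scored_cells
        if labeled == "line":
            f_line = f_lab
        else:
            f_line = 1.0 - f_lab
        q_line = true_index * f_line / (true_index * f_line + (1.0 - f_line))
        q_labeled = q_line if labeled == "line" else 1.0 - q_line
        s_labeled = int(rng.binomial(n_scored_spores, q_labeled * ret))
        if labeled == "line":
            assay = CompetitionAssay(
                line_id=line_id, labeled_strain="line",
                N_line=n_labeled_cells, N_anc=n_scored_cells - n_labeled_cells,
                S_line=s_labeled, S_anc=n_scored_spores - s_labeled,
                retention=ret,
            )
        else:
            assay = CompetitionAssay(
                line_id=line_id, labeled_strain="ancestor",
                N_line=n_scored_cells - n_labeled_cells, N_anc=n_labeled_cells,
                S_line=n_scored_spores - s_labeled, S_anc=s_labeled,
                retention=ret,
            )
        assays.append(assay)
    return assays


# -- full experiment --------------------------------------------------------


def _competition_replicate(true_index, design, rng, line_id):
    assays = simulate_competition_counts(
        max(true_index, 1e-6),
        n_scored_cells=design.competition_cells_scored,
        n_scored_spores=design.competition_spores_scored,
        rng=rng, line_id=line_id,
    )
    idx, _ = aggregate_reciprocal(
        competition_index(assays[0]), competition_index(assays[1])
    )
    return idx


def simulate_ma_experiment(
    params: dict[str, MutationModelParams] | None = None,
    design: DesignSpec | None = None,
    seed: int | None = None,
    multiplicative: bool = False,
):
    """Simulate a full MA experiment.

    Parameters
    ----------
    params : dict trait -> MutationModelParams (default: study conditions)
    design : DesignSpec (default: 90 MA + 10 control lines, study replicate
        structure)
    seed : int, overrides design.seed
    multiplicative : bool, use the product-of-(1+a) line-value variant

    Returns
    -------
    (table, truth) : (FitnessTable, dict)
        truth maps line_id -> trait -> {"n_mutations", "effect_sum",
        "true_value"}; traits mutate independently (no built-in pleiotropy).
    """
    params = default_params() if params is None else params
    design = DesignSpec() if design is None else design
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    records = []
    truth: dict[str, dict[str, dict]] = {}
    G = next(iter(params.values())).G

    def add(line_id, group, trait, rep, value):
        records.append(
            dict(line_id=line_id, group=group, trait=trait,
                 block=np.nan, replicate=rep, value=float(value))
        )

    line_ids = [f"MA{i + 1:03d}" for i in range(design.n_ma)]
    ctrl_ids = [f"C{i + 1:02d}" for i in range(design.n_control)]

    for trait in TRAITS:
        if trait not in params:
            continue
        p = params[trait]
        n_anc = design.ancestor_reps.get(trait, 10)
        reps = design.reps_per_line.get(trait, 1)

        # ancestor replicates: mutation-free, true value 1
        if trait == "spore_germination":
            for i in range(n_anc):
                counts = simulate_germination_counts(
                    ANCESTRAL_GERMINATION_RATE, plates=1,
                    spores_per_plate=design.germination_spores_per_plate, rng=rng)
                add("ANC", "ancestor", trait, i,
                    counts[0] / design.germination_spores_per_plate)
        elif trait == "competitive_ability":
            for i in range(n_anc):
                add("ANC", "ancestor", trait, i,
                    _competition_replicate(1.0, design, rng, "ANC"))
        else:
            noise = rng.normal(0.0, p.sigma_env, size=n_anc)
            for i in range(n_anc):
                add("ANC", "ancestor", trait, i, 1.0 + noise[i])

        # MA and control lines
        for group, ids, u_scale in (
            ("MA", line_ids, 1.0),
            ("control", ctrl_ids, design.control_retention),
        ):
            if not ids:
                continue
            p_grp = replace(p, U=p.U * u_scale)
            counts, sums, effects = draw_line_effects(p_grp, len(ids), rng)
            true_vals = true_line_value(sums, effects, multiplicative)
            for i, lid in enumerate(ids):
                truth.setdefault(lid, {})[trait] = {
                    "n_mutations": int(counts[i]),
                    "effect_sum": float(sums[i]),
                    "true_value": float(true_vals[i]),
                }
                if trait == "spore_germination":
                    rate = float(np.clip(
                        ANCESTRAL_GERMINATION_RATE * true_vals[i], 0.0, 1.0))
                    cts = simulate_germination_counts(
                        rate, plates=reps,
                        spores_per_plate=design.germination_spores_per_plate,
                        rng=rng)
                    for r in range(reps):
                        add(lid, group, trait, r,
                            cts[r] / design.germination_spores_per_plate)
                elif trait == "competitive_ability":
                    for r in range(reps):
                        tv = true_vals[i] + rng.normal(0.0, p.sigma_env)
                        add(lid, group, trait, r,
                            _competition_replicate(tv, design, rng, lid))
                else:
                    for r in range(reps):
                        add(lid, group, trait, r,
                            true_vals[i] + rng.normal(0.0, p.sigma_env))

    df = pd.DataFrame(records)
    table = FitnessTable(df=df, G=G)
    return table, truth
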