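# Methods

`mafitkit` analyses mutation-accumulation (MA) experiments on fitness
traits: lineages propagated through repeated single-cell bottlenecks so that
spontaneous mutations accumulate nearly free of selection, then scored for a
panel of fitness components alongside the unmutated ancestor and a set of
control lines kept at larger population size.  The reference design the
package emulates is the *Dictyostelium discoideum* experiment with 90 MA
lines, 10 control lines, eight fitness components (plate growth, liquid
growth, slug distance, fruiting-body count, spores per fruiting body, total
spores, spore germination, competitive ability), 9–42 ancestor replicates
per trait, and G = 994 cell generations of accumulation.

## Data model and normalization

All stages operate on a long-format replicate-level table
(`line_id, group, trait, block, replicate, value`).  Relative fitness is the
measurement divided by the ancestor mean for that trait; ancestor replicates
are pooled across assay blocks before taking the mean (a per-block mode
exists but is off by default, since block effects are screened with
Kruskal–Wallis tests and pooled only when non-significant).  MA and control
group statistics are computed over per-line means (replicates averaged
first); ancestor statistics over replicates.  Sample variances use divisor
n−1 throughout, and a variance from a single value is reported as undefined,
never as zero.  Plate growth is converted at ingestion from plaque cell
counts to doublings, log2(cell number).

## Mutational model

The generative model shared by the simulator and the likelihood is a
compound Poisson process: a line carries k ~ Poisson(M) mutations with
M = U·G, where U is the per-haploid-genome per-generation rate of
fitness-altering mutations.  Each mutation's effect magnitude is gamma
distributed with shape β and rate α (mean effect E(a) = β/α), reflected
around zero: positive with probability P (the beneficial fraction),
negative otherwise.  A line's true relative fitness is 1 + Σ effects
(additive; a multiplicative Π(1+a) variant is available for robustness
studies), and every replicate adds Normal(0, σ_env²) assay error.

### Moment identities

E[shift] = M(2P−1)β/α and Var[shift] = Mβ(β+1)/α²; these are the test
oracles for the simulator and the basis of the moment-matching starts for
the optimizer.

## Synthetic data

`simulate_ma_experiment` reproduces the reference design by default:
ancestor replicate counts per trait as in the study, five plate-growth
plaques, two 100-spore germination plates, and two reciprocal competition
mixes per line.  Germination and competitive ability are generated as
binomial counts (germinated spores per plate; labeled cells of ≥500 scored
and labeled spores of ≥500 scored) and converted to proportions/indices, so
downstream code sees the same schema as real data.  Germination true rates
are capped at 1.0 before sampling — a beneficial mutation cannot push a
proportion past 100% — while the standalone count simulator refuses
out-of-range rates outright.  Default σ_env per trait is calibrated to the
observed ancestor replicate variances (e.g. liquid growth 0.0011); default
(U, E(a), P) per trait follow the published per-trait estimates where the
data identified them.

Control lines are modeled phenomenologically with a retention factor
κ ∈ [0,1] scaling their mutational input (U·κ); κ = 0.2 by default, chosen
once so that control means fall between ancestor and MA lines as observed —
no quantitative control-line model was ever published, and the package does
not simulate within-plate selection dynamics.  What the generator does not
emulate: pleiotropy (traits mutate independently unless a shared channel is
enabled), block structure, genotype-by-environment interaction, and
non-normal assay error.  Tests passing on synthetic data therefore validate
the estimators under the model's own assumptions, not against every feature
of real data.

## Group statistics

Group mean comparisons use two-sided Wilcoxon rank-sum tests with midranks;
for combined n ≤ 20 the null distribution of the rank sum is enumerated
exactly over all splits (ties included), larger samples use the
tie-corrected normal approximation.  Variance comparisons use a
median-centered rank Levene test: subtract each group's median, pool,
convert to midranks, then run a classical Levene analysis (absolute
deviations of ranks from group means) on the ranked values.  Outlier
screening flags replicates more than k SD (default 4) from the mean in a
single pass.  Multiple-comparison adjustment is Benjamini–Hochberg across
the per-comparison-type battery of eight traits (Bonferroni available).

Per-line calls compare each line's mean to
ancestor_mean ± z·ancestor_SD with z the two-sided normal quantile at
α/family; the family defaults to all tested lines (90 MA + 10 control =
100, giving z = 3.48 at α = 0.05) and is configurable.

## Bateman–Mukai estimation

With ΔM the decline in mean and ΔV the inflation of among-line variance,
E(a) = ΔV/ΔM and U = (ΔM²/ΔV)/G.  The estimate is withheld (with a reason
code) unless ΔM > 0, ΔV > 0 and ΔM > ΔV — the literal applicability screen
used in the reference analysis, kept literal because it reproduces the two
withheld cells there.  The method assumes equal deleterious effects; under
dispersed (gamma) effects it underestimates U and overestimates E(a), a
direction the test suite asserts on synthetic data.

## Maximum likelihood

The line-mean density is the Poisson mixture over k of
binomial-over-beneficial-count convolutions of gamma differences with the
Gaussian error kernel.  The (k, j) sum collapses in Fourier space: the
summed-effect CF is c(t)^k with
c(t) = P(1−it/α)^(−β) + (1−P)(1+it/α)^(−β), so the package evaluates the
truncated sum Σ_{k≤kmax} Pois(k; M) c(t)^k, multiplies by the Gaussian CF,
and inverts by trapezoidal quadrature at the observed values.  Numerical
choices:

- k truncation: smallest k with Poisson upper-tail < 1e−10, capped at 60;
  hitting the cap warns.  The U search ceiling is two thirds of the cap
  divided by G (U ≤ 0.040 at G = 994): beyond it the truncated sum loses
  real Poisson mass and the likelihood is biased low, so instead of
  evaluating a corrupted likelihood there, an interval endpoint reaching
  this bound is reported open (∞) — the same semantics as a flat ridge
  running past the searched range.
- Quadrature step 2π/L with aliasing period L = 2·max|z−1| + 12 in
  relative-fitness units.  Trapezoidal CF inversion equals the Fourier
  series of the L-periodized density, so the only inversion errors are
  aliased tail mass beyond L and the CF truncation at
  t_max = √(2·ln 1e16)/σ_min; both are driven below 1e−4, verified against
  normalization integrals and a 10⁶-draw Monte-Carlo oracle.
- σ_env is estimated jointly, anchored by the ancestor replicates treated
  as mutation-free Normal(1, σ_env²) observations; its search floor is a
  quarter of the ancestor SD (densities need a positive noise scale for the
  inversion grid to terminate).
- Optimization is over (log U, log α, log σ) with Nelder–Mead from three
  deterministic starts (a moment-matching start and two ×5 perturbations),
  independently in every cell of a fixed (β, P) grid — by default the 60
  combinations of β ∈ {0.1, 0.5, 1, 2, 3, 4, 6, 8, 10, 50} and
  P ∈ {0, 0.1, 0.2, 0.3, 0.4, 0.5} — followed by midpoint refinement
  around the best cell (P may exceed 0.5 during refinement).

Support intervals are 2-log-unit profile intervals.  The profile for U (and
for E(a), parameterized through α at fixed β) re-maximizes the nuisance
parameters at each grid value, walking outward from the point estimate with
warm starts, and takes the envelope over every (β, P) cell whose own
maximum lies within 2 log units of the global one — conditioning on the
single best cell demonstrably understates the uncertainty.  Crossings are
located by bisection with the nuisances re-optimized at every probe.  An
endpoint coinciding with a search bound is flagged open and reported as 0
or ∞; an open upper U end together with a shrinking E(a) is the classic MA
likelihood ridge (many tiny effects indistinguishable from fewer large
ones), surfaced as a `ridge` flag rather than a hard failure, and a
`flat_surface` flag marks grids whose entire log-likelihood range is under
2 units.  An equal-effects variant (single magnitude a, offsets (2j−k)a)
is fitted per P over (U, a, σ).

The package reports the flat-ridge diagnostics and leaves the decision to
abandon a fit to the analyst.  Line means (not replicate-level values) enter
the likelihood by default.

## Pleiotropy

Trait correlation uses pairwise Spearman coefficients (midranks) with BH
adjustment.  The effective number of traits is N_eff = N − Var(λ) over the
eigenvalues of the correlation matrix, with Var(λ) using divisor N (the
eigenvalue mean is exactly 1; the N−1 divisor is config-exposed and changes
nothing at the reported precision).  Per-component mutation rates invert
the unaffected fraction, (1−μ)^G = (n−k)/n.

Two randomization tests probe independence of components across lines.
Test A reassigns each trait's observed number of significant lines
uniformly without replacement; test B draws per-line per-trait
Poisson(G·μ̂) mutation counts.  In both, each simulated dataset's category
counts (lines with 0–8 affected components) are Pearson-χ²-tested against
the analytic independence expectation — the Poisson-binomial pmf of the
per-trait affect probabilities scaled by the number of lines, with all nine
categories kept (df = 8, no pooling) — and the fraction of simulations
exceeding the 5% critical value is reported.  Testing each simulation
against its own counts as "expectation" is not executable: single-run
expectations contain empty cells wherever the observed count is positive,
making almost every comparison infinite.  The analytic Poisson-binomial
expectation is also the exact large-simulation limit of both tests, which
the suite asserts.

The ad-hoc lower bound on U from "every line carries at least one
mutation" admits two readings of the defining tail probability; both are
solved by root-finding and returned ((1−e^(−UG))^n equal to 0.05 or 0.95,
giving UG ≈ 3.42 and ≈ 7.47 for n = 90) rather than silently choosing one.
The stabilizing-selection check fits a least-squares cubic of total spores
against a component, tests the cubic against the linear model by F-test,
and reports an interior local maximum of the fitted curve when one exists.

## Competition index

C = (S_line/S_anc)/(N_line/N_anc) from labeled-spore chimera counts; the
line-level index averages the two reciprocal labelings, and a single
available mix is returned with a coverage flag.  No dye-retention
correction is applied by default (retention ~99.2% was reported but no
correction stated); an optional correction divides the labeled fraction by
the retention rate.  A zero ancestor spore count yields an undefined index,
not infinity.

## Problem sizes and test design

The acceptance surface for the likelihood machinery is property-based
(normalization, Monte-Carlo oracle equivalence, parameter recovery, ridge
detection) because the underlying 90-line trait values were never
published.  Parameter recovery runs 20 seeded 90-line replicates at a
reduced grid (β ∈ {0.5, 1, 2, 4, 10}, P ∈ {0, 0.1, 0.2, 0.3, 0.5}, no
refinement, two starts) — the package's standard reduced setting for
simulation studies; point estimates and intervals at the full grid differ
only marginally on well-identified data.  Randomization tests use 1000
replicates with fixed seeds, matching the reference procedure.

## Known limitations

- The likelihood treats line means as exchangeable with a single σ_env;
  unequal replicate counts per line are not propagated into per-line error
  variances.
- P is profiled on the grid envelope only, so its interval resolution is
  the P grid spacing.
- The BM applicability screen compares ΔM with ΔV literally, a
  unit-inconsistent but historically faithful rule.
- Count-based traits (germination, competition) are analysed on the same
  Gaussian-error likelihood as continuous traits, as in the reference
  analysis; a proper binomial observation model is out of scope.
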