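# mafitkit

Analysis toolkit for mutation-accumulation (MA) experiments on fitness
traits, built around the 90-line *Dictyostelium discoideum* design: lineages
bottlenecked to a single cell every transfer for G = 994 cell generations,
then scored for eight fitness components against the ancestor and ten
control lines.

The package estimates the rate and distribution of effects of spontaneous
fitness-altering mutations from such data:

- **Group statistics** — Wilcoxon rank-sum mean comparisons, median-centered
  rank Levene variance tests, Kruskal–Wallis block screens, outlier
  screening, and per-line significance calls against Bonferroni-corrected
  normal confidence bands around the ancestor.
- **Bateman–Mukai estimation** — from the decline in mean ΔM and the
  inflation of among-line variance ΔV: E(a) = ΔV/ΔM and U = (ΔM²/ΔV)/G,
  with the classical applicability screen.
- **Maximum likelihood** — a compound-Poisson model: k ~ Poisson(U·G)
  mutations per line, effect magnitudes gamma(β, α) reflected around zero
  with beneficial fraction P, Gaussian assay error σ_env.  Fitted by a
  (β, P) grid profile with 2-log-unit support intervals and open-endpoint
  (ridge) diagnostics.
- **Pleiotropy** — Spearman correlation structure, the effective number of
  traits N_eff = N − Var(λ) from correlation-matrix eigenvalues,
  per-component mutation rates via (1−μ)^G inversion, and two randomization
  tests of trait independence with a Poisson-binomial analytic null.
- **Competition index** — C = (S_line/S_anc)/(N_line/N_anc) from
  labeled-spore chimera assays, reciprocal mixes averaged.
- **Synthetic data** — a generator reproducing the full experimental design
  (line counts, replicate structure, binomial germination and competition
  counts) with known ground truth, so every estimator is testable without
  any download.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

```python
import numpy as np
from mafitkit import (simulate_ma_experiment, relative_fitness, summarize,
                      classify_lines, bm_estimate, fit_ml)
from mafitkit.groupstats import count_calls
from mafitkit.simulate import params_for_mean_effect

# a liquid-growth-like trait: U = 0.002 mutations/genome/generation,
# mean effect 0.15, 10% beneficial, assay SD 0.03
params = {"liquid_growth": params_for_mean_effect(
    U=0.002, mean_effect=0.15, beta=1.0, P=0.1, sigma_env=0.03)}
table, truth = simulate_ma_experiment(params, seed=1)

rel = relative_fitness(table)
s = summarize(rel, "liquid_growth")
print(f"MA mean {s['MA'].mean:.3f}, among-line variance {s['MA'].variance:.4f}")

calls, bounds = classify_lines(rel, "liquid_growth")
print(f"bounds ({bounds[0]:.3f}, {bounds[1]:.3f}), low/high {count_calls(calls)}")

est = bm_estimate((s['ancestor'].mean, s['ancestor'].variance),
                  (s['MA'].mean, s['MA'].variance), G=994)
print(f"BM: E(a) = {est.E_a:.3f}, U = {est.U_per_gen:.4f}")

fit = fit_ml(rel.ancestor_values("liquid_growth"),
             rel.line_means("liquid_growth", "MA").to_numpy(), G=994)
print(fit.summary())
```

prints (seed 1):

```
MA mean 0.798, among-line variance 0.0704
bounds (0.936, 1.064), low/high (62, 5)
BM: E(a) = 0.347, U = 0.0006
Mutation-effects ML fit (reflected gamma model)
  log-likelihood: 43.634
  U      = 0.00368 /genome/generation (0.00258 - 0.0214)
  E(a)   = 0.0831 (0.0162 - 0.117)
  P      = 0.15 (0.0966 - 0.246)
  sigma  = 0.0177
  beta   = 0.5, alpha = 6.01
```

The MA lines declined ~20% in mean fitness and 67 of 90 fall outside the
ancestor band.  Bateman–Mukai, which assumes equal effects, shows its
documented bias under dispersed effects (rate 0.0006 vs the generating
0.002, effect 0.35 vs 0.15).  The likelihood fit illustrates the classic MA
trade-off instead: this dataset is explained almost as well by more,
smaller mutations, so the fit lands at higher U and lower E(a) than the
generating values while their product — the mean decline per generation,
U·E(a) ≈ 3.1e-4 vs the true 3.0e-4 — is pinned down precisely, and the wide
upper support end for U (0.0214) flags the ridge.  Across seeded
replicates the 2-log-unit intervals cover the generating U and E(a) at
roughly their nominal rate (see the parameter-recovery test).

A command-line interface mirrors the stages
(`ma-fitkit simulate | group-stats | bm | ml-fit | pleiotropy | competition
| run`).

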