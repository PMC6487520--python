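# seedbo — Bayesian optimization of seed-germination conditions

`seedbo` is a closed-loop experiment-design toolkit for germination trials in
climate chambers. A grower (or an automated bench) controls a handful of
set-points — air temperatures on successive days, amounts of water supplied at
fixed times — places N seeds per chamber, and counts outcomes after each
multi-day trial. `seedbo` suggests the next batch of chamber settings so that
germination efficiency improves as quickly as the trial budget allows, without
any mechanistic model of the seeds.

## The score and its noise model

Each run counts `N_g` germinated seeds (radicle emerged; the count *includes*
well-germinated seeds) and `N_wg` well-germinated seeds (stricter criterion).
The optimized target is

```
y = (N_g + N_wg) / N  ∈ [0, 2],        efficiency = y / 2 × 100 %
```

Modeling one seed as a two-stage Bernoulli trial — germinate with probability
p(x), then well-germinate with probability q(x) — gives, for large N,

```
y ~ N(μ, σ²/N),   μ = p(1+q),   σ² = p(1+3q) − p²(1+q)².
```

Since max σ² over the unit square is 1 (at p = ½, q = 1), the observation
noise is bounded below by 1/N; conditioning on the observed score tightens it
to y(2−y)/N per observation. Both floors are available and feed the surrogate.

## The optimizer

The surrogate is a constant-mean Gaussian process with kernel
`k(xᵢ,xⱼ) = α·C₅⁄₂(xᵢ/ρ, xⱼ/ρ) + σ²δᵢⱼ` (isotropic Matérn, ν = 5/2, plus white
noise), fitted by maximum marginal likelihood with multi-start search;
temperatures are scaled to [0, 1] and water to [0, 0.5] so 1 °C ≡ 12.5 ml for
the isotropic kernel. The next condition maximizes the upper confidence bound
`μ̂(x) + κ·σ̂(x)` subject to two distance constraints: every suggestion must
move at least ε_xploit (0.1 °C / 1 ml) from each tested condition in some
coordinate (no sub-precision repeats), and at most ε_xplore (10 °C / 100 ml)
in total from the nearest trusted condition (no leaps into known-bad
territory). κ can be fixed or chosen automatically (smallest grid value whose
maximizer already satisfies both constraints). Concurrent chambers are filled
by fantasy updates: each suggestion is provisionally "observed" at its GP
predictive mean before picking the next, and all fantasies are discarded
afterwards. Optimization kicks off from box-corner pseudo-observations
(extreme conditions score 0) plus an expert guess.

A synthetic germination simulator (smooth p(x), q(x) surfaces + binomial
sampling) exercises the full loop without a laboratory.

## Worked example

Simulate the 7-parameter pea-style campaign (16 corner points, 1 expert
guess, 11 trials × 3 chambers, 100 seeds per run) against the built-in
synthetic surface:

```
$ seedbo simulate --surface pea7d --trials 11 --batch 3 --seed 1 \
      --restarts 8 --out pea_sim.csv --summary pea_sim.json
pea7d: 50 observations, best score 1.130 (expert 0.390)
```

The per-trial running maximum in `pea_sim.json` shows the climb from the
expert guess (score 0.39, i.e. 19.5 % efficiency) to 1.13 (56.5 %):

```
running max: [0.55, 0.55, 0.55, 0.55, 0.55, 0.65, 0.74, 0.81, 0.83, 0.87, 1.13]
best_x: t1=23.2 t2=20.8 t3=22.9 t4=21.3 °C, w1=w2=w3=132 ml
```

The same arithmetic applied to the published pea campaign ledger shipped with
the package:

```python
from seedbo import Session, pea_config
from seedbo.datasets import pea_ledger

rep = Session(pea_config(), ledger=pea_ledger()).report()
print(rep["initial_y"], rep["best_y"], rep["improvement_percent"])
# 0.73 1.13 55        (efficiency 36.5 % -> 56.5 %)
```

For a lab session, `seedbo init` seeds the ledger with corner points,
`seedbo suggest` proposes the next chamber settings, `seedbo observe` records
counted outcomes, and `seedbo report` / `seedbo export` summarize progress.

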