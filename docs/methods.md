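# Methods

## Target score and noise model

A germination run places N seeds under one condition x and counts N_g
germinated seeds (radicle emerged; inclusive of well-germinated) and N_wg
well-germinated seeds. The target is y = (N_g + N_wg)/N ∈ [0, 2]. The
inclusive counting convention is load-bearing: it is what makes counts such
as (73 germinated, 18 well) map to 0.91 and (80, 33) to 1.13.

Treating a seed as a two-stage Bernoulli trial — germinate w.p. p, then
well-germinate w.p. q — the score of a single seed is 0, 1 or 2 with mean
μ = p(1+q) and variance σ² = p(1+3q) − p²(1+q)²; averaging N seeds gives
Var[y] = σ²/N and a normal approximation for large N. Two identities used
throughout, both verified by grid and Monte-Carlo oracles in the tests:

* max over the unit square of σ² is exactly 1, attained at (p, q) = (½, 1),
  so σ²/N ≤ 1/N — the **global noise floor** that becomes the lower bound of
  the white-noise hyperparameter (0.01 for N = 100);
* μ(2−μ) − σ² = p(1−q) ≥ 0, so y(2−y)/N is the supremum of the noise
  variance over all (p, q) consistent with an observed mean — the
  **per-observation floor**.

Both floors are implemented. The default noise mode is "global" (the floor
enters only through the σ² bound); "per_obs" replaces the GP diagonal with
max(σ², floor_i). They are alternatives, not additive, which avoids counting
the same noise twice. The normal approximation is not gated on N; the exact
binomial sampler in the simulator is the reference for its quality.

## Parameter space and scaling

Parameters carry physical bounds (0–40 °C, 0–250 ml), a linear map onto
[0, scaled_high] (1.0 for temperature, 0.5 for water, making 1 °C ≡ 12.5 ml
for the isotropic kernel), per-parameter distance thresholds ε_xploit
(0.1 °C / 1 ml) and ε_xplore (10 °C / 100 ml), and a device precision
(0.1 °C / 1 ml) to which every suggestion is rounded *after* optimization,
in physical units; the rounded point is what gets logged and re-checked
against the constraints. For temperature-only campaigns the same [0, 1]
scaling is kept for numerical conditioning even though a single unit would
not strictly require it.

Initialization enters 2^d box corners (temperatures at {0, 40} °C, water
pinned at 0) as pseudo-observations with score 0 — extreme conditions
germinate nothing — tagged `init` so they can be excluded from the trusted
exploration subset.

## Gaussian-process surrogate

Kernel: k(xᵢ,xⱼ) = α·C₅⁄₂(‖xᵢ−xⱼ‖/ρ) + σ²δᵢⱼ with ν = 5/2 Matérn; constant
mean fixed to the mean of the training targets before fitting. Hyperparameter
boxes default to α, ρ ∈ [10⁻⁵, 10⁵] and σ² ∈ [1/N, 10⁵]. Fitting maximizes
the log marginal likelihood with L-BFGS-B in log-hyperparameter space from 30
starts (one moderate default, the rest log-uniform over the boxes); the local
optimizer choice is ours, the restart count is the protocol's. A 10⁻¹⁰ jitter
stabilizes the Cholesky factorization and is not a model parameter.
Predictive variance is that of the latent response (no σ² at the query), so
it reverts to α far from data; it is clipped at zero against round-off.
Hyperparameters are refitted when real observations arrive, never inside a
suggestion batch.

With few, conflicting observations (e.g. corner zeros plus one good expert
point) the marginal likelihood genuinely prefers a white-noise-only
explanation (tiny ρ, large σ²); the posterior is then nearly flat and early
suggestions are close to constrained random search. This is intrinsic to the
model, not an optimizer failure — we verified the degenerate optimum
dominates smooth settings on such data — and it resolves itself once a few
informative trials accumulate.

## Acquisition and constraints

UCB a(x, κ) = μ̂(x) + κσ̂(x). The exploitation constraint demands a Chebyshev
distance of at least ε_xploit from every tested condition; the exploration
constraint a Manhattan distance of at most ε_xplore from the nearest member
of a trusted subset (default: everything except `init` rows). Because the
thresholds are per-quantity, each coordinate difference is divided by its own
ε before the norm is taken and compared to 1; with one shared unit this
reduces exactly to the scalar form. Slacks are reported on every suggestion.

Fixed-κ suggestions run SLSQP from multiple starts (random box points plus
the incumbent best) with both constraints enforced; the best feasible local
maximum wins, ties broken toward the lexicographically smallest scaled point,
and if no start is feasible the best infeasible point is returned flagged.
Automatic κ scans an ascending grid (default 0 to 10, step 0.25) and returns
the first κ whose *unconstrained* maximizer already satisfies both
constraints — the smallest feasible κ prefers exploitation. Note the
distinction: enforcing the constraints inside the solver at every κ would
make the first grid value always win, defeating the scan, so feasibility is
tested on the natural maximizer instead.

Batches for B concurrent chambers use fantasy updates: suggest, condition a
copy of the GP on the suggestion's own predictive mean (fantasy noise floor
1/N, inconsequential in global mode where σ² ≥ 1/N already), repeat.
Fantasies join the observed set — making batch members mutually
exploit-feasible — but never the ledger, and the caller's fit object is
never mutated.

## Synthetic ground truth

The simulator draws G ~ Binomial(N, p(x)) then W ~ Binomial(G, q(x)), so its
moments match the analytic model exactly. The built-in surfaces are declared
fixtures with constants fixed in code; they emulate qualitative features a
grower would recognize — a mid-20s °C sweet spot, a benefit from a mild
day/night temperature swing, a moderate cumulative water optimum (water
demand saturates rather than growing without bound) — and make no claim to
reproduce pea or radish biology. What passing closed-loop tests show is that
the machinery finds optima of smooth two-stage Bernoulli surfaces under
realistic trial noise; they say nothing about any particular cultivar.

* `pea7d`: p peaks at mean schedule 25 °C and scaled total water 0.74
  (≈ 370 ml over three waterings), q rewards a ≈ 6 °C alternating swing;
  peak expected score 1.445.
* `radish4d`: temperature-only, p up to 0.98 at mean 24 °C, q up to 0.95
  with a weak preference for a ≈ 5 °C swing; peak expected score ≈ 1.91,
  matching a high-efficiency campaign where constant-temperature baselines
  already score ≈ 1.73–1.84.
* `unimodal_1d`: single Gaussian bump centered at 24 °C (scaled 0.6) with
  closed-form optimum 0.9 × 1.6 = 1.44, used by grid-oracle tests.

Randomness derives from one session seed; each (trial, chamber, repetition)
gets a child stream via `SeedSequence([seed, trial, chamber, rep])`, so
chamber ordering cannot perturb results and ledgers are bit-reproducible.

## Closed-loop evaluation choices

The loop tests mirror the two campaign shapes: 16 corner points + 1 expert
point + 11 trials × 3 chambers at N = 100 (7-D), and 8 sequential trials on
the 1-D surface. Every campaign in this design starts from an expert guess,
so the 1-D run starts from 20 °C (a sensible but suboptimal guess, expected
score ≈ 1.10). Loop runs use 8 marginal-likelihood restarts per refit and 6
acquisition multistarts — problem sizes chosen to keep the full 10-seed
suite comfortably interactive; success rates were not sensitive to raising
either. The 7-D criterion is an improvement property (best found beats the
expert score in ≥ 8/10 seeds), not a trajectory match: real campaign
trajectories depend on live biology and per-step operator choices of κ and
are not reproducible.

## Numerical details and edge cases

* Efficiency percentages are printed with half-up rounding at one decimal
  (1.903/2 → 95.2, 1.835/2 → 91.8); improvement percent is rounded to the
  nearest integer.
* Replicated inputs with disagreeing targets are legal; the white-noise term
  absorbs the spread.
* An empty exploration subset raises with guidance to widen the rule rather
  than silently dropping the constraint.
* Precision rounding can in principle move a boundary-feasible suggestion by
  up to half a device step; slacks and the feasible flag are therefore
  recomputed on the rounded point, and that honest flag is what callers see.
* Ledger CSVs round-trip byte-identically (timestamps excluded); fantasy
  rows are refused at the ledger layer.

## Known limitations

* Isotropic kernel only — no per-dimension length scales; the scaling map is
  the only anisotropy control, as in the protocol.
* The κ grid bounds are a design default; nothing adapts them to the data.
* Early-campaign behavior is close to constrained random search until the
  marginal likelihood escapes the white-noise optimum (see above).
* No mechanistic seed physiology (e.g. triphasic water uptake) is modeled;
  the simulator is a testing instrument, not a digital twin.
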