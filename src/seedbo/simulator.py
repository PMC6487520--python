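"""Synthetic germination ground truth and the closed experiment loop.

Real germination trials take days of chamber time; everything downstream of
the chamber is exercised here against declared synthetic response surfaces.
A :class:`GroundTruth` holds two smooth maps over the scaled condition box --
p(x), the probability that a seed germinates, and q(x), the probability that
a germinated seed reaches the well-germinated stage -- and a trial draws

    G ~ Binomial(N, p(x)),   W ~ Binomial(G, q(x)),

so the simulated score (G + W)/N has exactly the two-stage Bernoulli moments
of the analytic noise model.  The built-in surfaces are fixtures with
constants documented in code: they emulate qualitative features a grower
would expect (a mid-20s degC sweet spot, benefit from a mild day/night
temperature swing, moderate cumulative water) and make no claim to pea or
radish biology.

``run_closed_loop`` executes the full protocol -- corner initialization,
optional expert point, then fit / suggest-batch / simulate / ingest rounds --
writing every real observation to a trial ledger.  Randomness derives from a
single session seed; each (trial, chamber, repetition) gets its own child
stream via ``SeedSequence([seed, trial, chamber, rep])`` so chamber order
cannot perturb the draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .acquisition import suggest_batch
from .config import ExperimentConfig
from .germination_score import (GerminationCount, append_ledger_row, empty_ledger,
                                noise_floor_for, target_score)
from .gp_model import fit_mle
from .parameter_space import (ParameterSpace, ParameterVector, ValidationError,
                              corner_init_points, pea_space, radish_space,
                              single_temperature_space)

__all__ = ["GroundTruth", "SimTrialResult", "builtin_surfaces", "simulate_trial",
           "run_closed_loop"]


@dataclass(frozen=True)
class GroundTruth:
    """Synthetic response surfaces over a parameter space's scaled box."""

    space: ParameterSpace
    p_surface: Callable[[np.ndarray], float]
    q_surface: Callable[[np.ndarray], float]
    description: str
    optimum_hint: Optional[np.ndarray] = None   # scaled argmax of p(1+q), if known

    def score_surface(self, x_scaled) -> float:
        """Noise-free expected score p(x) * (1 + q(x))."""
        x = np.asarray(x_scaled, float)
        return float(self.p_surface(x) * (1.0 + self.q_surface(x)))


@dataclass(frozen=True)
class SimTrialResult:
    count: GerminationCount
    x: ParameterVector
    rng_seed: tuple[int, ...]


def _bump(x, center, width):
    return np.exp(-0.5 * ((x - center) / width) ** 2)


# Fixture constants for the built-in surfaces.  Temperatures enter through
# their scaled mean (Tbar) and the mean absolute step between consecutive
# set-points (osc, the day/night-like swing); water through the scaled total.
_PEA = dict(p_max=0.85, t_center=0.625, t_width=0.12,       # ~25 degC schedule mean
            w_center=0.74, w_width=0.35,                    # ~370 ml cumulative water
            q_max=0.70, osc_center=0.15, osc_width=0.08)    # ~6 degC swing helps q
_RADISH = dict(p_max=0.98, t_center=0.60, t_width=0.20,     # 24 degC mean is prime
               q_max=0.95, q_t_width=0.22,
               osc_center=0.12, osc_width=0.18)             # mild swing, weak effect
_UNI = dict(p_max=0.90, center=0.60, p_width=0.15,          # single bump at 24 degC
            q_max=0.60, q_width=0.20)


def _temp_features(tau: np.ndarray) -> tuple[float, float]:
    tbar = float(np.mean(tau))
    osc = float(np.mean(np.abs(np.diff(tau)))) if len(tau) > 1 else 0.0
    return tbar, osc


def builtin_surfaces(name: str) -> GroundTruth:
    """Named fixture surfaces: ``pea7d``, ``radish4d`` or ``unimodal_1d``."""
    if name == "pea7d":
        c = _PEA

        def p(s):
            tbar, _ = _temp_features(np.asarray(s)[:4])
            w = float(np.sum(np.asarray(s)[4:7]))
            return c["p_max"] * _bump(tbar, c["t_center"], c["t_width"]) * \
                _bump(w, c["w_center"], c["w_width"])

        def q(s):
            _, osc = _temp_features(np.asarray(s)[:4])
            return c["q_max"] * _bump(osc, c["osc_center"], c["osc_width"])

        # alternating schedule with mean t_center and swing osc_center; water
        # split evenly to hit w_center: the factorized maximum of p*(1+q)
        hint = np.array([0.55, 0.70, 0.55, 0.70] + [c["w_center"] / 3] * 3)
        return GroundTruth(pea_space(), p, q,
                           "7-D pea-like surface: mid-20s schedule, periodic swing, "
                           "moderate total water", hint)
    if name == "radish4d":
        c = _RADISH

        def p(s):
            tbar, _ = _temp_features(np.asarray(s))
            return c["p_max"] * _bump(tbar, c["t_center"], c["t_width"])

        def q(s):
            tbar, osc = _temp_features(np.asarray(s))
            return c["q_max"] * _bump(tbar, c["t_center"], c["q_t_width"]) * \
                _bump(osc, c["osc_center"], c["osc_width"])

        hint = np.array([0.54, 0.66, 0.54, 0.66])   # mean 0.60, swing 0.12
        return GroundTruth(radish_space(), p, q,
                           "4-D radish-like temperature surface, optimum mean score "
                           "near 1.9", hint)
    if name == "unimodal_1d":
        c = _UNI

        def p(s):
            return c["p_max"] * _bump(float(np.asarray(s)[0]), c["center"], c["p_width"])

        def q(s):
            return c["q_max"] * _bump(float(np.asarray(s)[0]), c["center"], c["q_width"])

        return GroundTruth(single_temperature_space(), p, q,
                           "single Gaussian bump at scaled 0.6 (24 degC); "
                           "peak score p_max*(1+q_max)", np.array([c["center"]]))
    raise ValidationError(
        f"unknown surface {name!r}; options: pea7d, radish4d, unimodal_1d")


def simulate_trial(gt: GroundTruth, x, n_seeds: int, rng_seed) -> SimTrialResult:
    """Two-stage Bernoulli germination run at condition ``x`` (physical units)."""
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    xv = x if isinstance(x, ParameterVector) else ParameterVector(tuple(np.asarray(x, float)), gt.space)
    s = xv.scaled
    p = float(np.clip(gt.p_surface(s), 0.0, 1.0))
    q = float(np.clip(gt.q_surface(s), 0.0, 1.0))
    seed = tuple(int(v) for v in np.atleast_1d(rng_seed))
    rng = np.random.default_rng(np.random.SeedSequence(list(seed)))
    g = int(rng.binomial(n_seeds, p))
    w = int(rng.binomial(g, q)) if g > 0 else 0
    return SimTrialResult(GerminationCount(n_seeds, g, w), xv, seed)


def run_closed_loop(
    gt: GroundTruth,
    config: ExperimentConfig,
    n_trials: int,
    *,
    batch_size: Optional[int] = None,
    repetitions: int = 1,
    rng_seed: int = 0,
    expert_point: Optional[Sequence[float]] = None,
):
    """Run the whole optimization protocol against a synthetic ground truth.

    Protocol: corner initialization (temperature dims at {low, high}, other
    dims pinned at 0, score 0), one optional expert-chosen condition, then
    ``n_trials`` rounds of hyperparameter refit, batch suggestion, and
    simulated germination with ``repetitions`` repeats per chamber.

    Returns ``(ledger, summary)`` where the ledger is the standard trial CSV
    frame and the summary carries per-trial best/mean scores, the running
    maximum, and the best condition found.
    """
    space = config.space
    if space.dim != gt.space.dim:
        raise ValidationError("config space dimension differs from ground truth")
    B = config.batch_size if batch_size is None else int(batch_size)
    N = config.seeds_per_trial
    ss = np.random.SeedSequence(int(rng_seed))
    rng_fit, rng_acq = [np.random.default_rng(s) for s in ss.spawn(2)]

    ledger = empty_ledger(space)
    X: list[np.ndarray] = []     # scaled inputs of real observations
    y: list[float] = []
    floors: list[float] = []
    is_init: list[bool] = []

    def ingest(trial_id, chamber_id, xv: ParameterVector, count, provenance):
        nonlocal ledger
        score = 0.0 if count is None else target_score(count)
        floor = noise_floor_for(score, N, config.noise_mode)
        ledger = append_ledger_row(ledger, space, trial_id=trial_id,
                                   chamber_id=chamber_id, provenance=provenance,
                                   x_physical=np.asarray(xv), count=count,
                                   y=score, noise_floor=floor)
        X.append(xv.scaled)
        y.append(score)
        floors.append(floor)
        is_init.append(provenance == "init")

    binary = [p.name for p in space.params if p.unit == "degC"]
    fixed = [p.name for p in space.params if p.unit != "degC"]
    for i, (pt, target) in enumerate(corner_init_points(space, binary, fixed)):
        assert target == 0.0
        ingest("init", f"c{i:02d}", pt, None, "init")

    if expert_point is not None:
        xv = ParameterVector(tuple(np.asarray(expert_point, float)), space)
        for r in range(repetitions):
            res = simulate_trial(gt, xv, N, (rng_seed, 0, 0, r))
            ingest("expert", f"r{r}", xv, res.count, "expert")

    acq = config.acquisition_config()
    per_trial = []
    for t in range(1, n_trials + 1):
        fit = fit_mle(np.array(X), np.array(y),
                      floors=np.array(floors) if config.noise_mode == "per_obs" else None,
                      bounds=config.kernel_bounds(), n_restarts=config.n_restarts,
                      rng=rng_fit)
        acq.batch_size = B
        real = ~np.array(is_init)
        subset = np.array(X)[real] if (config.explore_subset_rule == "exclude_init"
                                       and real.any()) else np.array(X)
        if config.explore_subset_rule == "top_k":
            order = np.argsort(np.array(y))[::-1][: config.explore_top_k]
            subset = np.array(X)[order]
        suggestions = suggest_batch(fit, acq, space, observed=np.array(X),
                                    explore_subset=subset, rng=rng_acq)
        scores_t = []
        for c, sugg in enumerate(suggestions, start=1):
            xv = ParameterVector(tuple(sugg.x), space)
            for r in range(repetitions):
                res = simulate_trial(gt, xv, N, (rng_seed, t, c, r))
                ingest(f"t{t:02d}", f"c{c}r{r}", xv, res.count, "bo")
                scores_t.append(target_score(res.count))
        per_trial.append({"trial": t, "best": max(scores_t),
                          "mean": float(np.mean(scores_t))})

    real_mask = ~np.array(is_init)
    real_y = np.array(y)[real_mask] if real_mask.any() else np.array([])
    running_max = list(np.maximum.accumulate([pt["best"] for pt in per_trial])) \
        if per_trial else []
    best_row = None
    if real_y.size:
        idx = np.flatnonzero(real_mask)[int(np.argmax(real_y))]
        best_row = ledger.iloc[idx]
    summary = {
        "n_observations": len(y),
        "per_trial": per_trial,
        "running_max": [float(v) for v in running_max],
        "best_y": float(real_y.max()) if real_y.size else None,
        "best_x": {n: float(best_row[n]) for n in space.names} if best_row is not None else None,
        "expert_y": float(ledger.loc[ledger["provenance"] == "expert", "y"].mean())
        if (ledger["provenance"] == "expert").any() else None,
        "true_optimum_hint_score": gt.score_surface(gt.optimum_hint)
        if gt.optimum_hint is not None else None,
    }
    return ledger, summary
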