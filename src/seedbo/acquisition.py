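"""UCB acquisition with distance-constrained maximization and batching.

The next condition to try maximizes the upper confidence bound

    a_UCB(x, kappa) = mu_hat(x) + kappa * sigma_hat(x)

over the scaled box, subject to two chamber-realism constraints:

* exploitation (Chebyshev): the suggestion must differ from every tested
  condition by at least eps_exploit in at least one coordinate -- otherwise
  the chamber cannot distinguish it from a repeat (e.g. 22.001 degC after
  22.000 degC);
* exploration (Manhattan): the suggestion must stay within a total budget
  eps_explore of the nearest member of a trusted subset of tested conditions
  (by default the manually initialized corner points are excluded from that
  subset, so exploration hugs regions known to germinate).

Each threshold is per-parameter (0.1 degC and 1 ml; 10 degC and 100 ml), so
coordinate differences are divided by their own eps before the norm is taken
and compared to 1; with a single unit this reduces to the scalar form.

``select_kappa`` automates the operator's choice of kappa: ascending over a
grid, the *unconstrained* UCB maximizer is computed and the first kappa whose
maximizer already satisfies both constraints wins (small kappa = exploitation
preferred).  ``suggest_batch`` fills concurrent chambers by the fantasy
("kriging believer") scheme: after each suggestion the GP is conditioned on
its own predictive mean at that point, without re-optimizing hyperparameters,
and all fantasies are discarded once the batch is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .gp_model import GPFit
from .parameter_space import ParameterSpace, ValidationError

__all__ = [
    "AcquisitionConfig",
    "Suggestion",
    "EmptySubsetError",
    "ucb",
    "exploit_metric",
    "explore_metric",
    "maximize_ucb",
    "select_kappa",
    "suggest_batch",
]

_FEAS_TOL = 1e-6


class EmptySubsetError(ValidationError):
    """The exploration subset is empty; widen explore_subset_rule."""


def _default_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 10.0 + 1e-9, 0.25), 10))


@dataclass
class AcquisitionConfig:
    """Settings for suggestion generation.

    kappa may be a fixed nonnegative number or "auto", in which case
    ``kappa_grid`` is scanned ascending for the first value whose maximizer
    respects both distance constraints.
    """

    kappa: float | str = "auto"
    kappa_grid: tuple[float, ...] = field(default_factory=_default_grid)
    batch_size: int = 3
    explore_subset_rule: str = "exclude_init"
    explore_top_k: Optional[int] = None
    n_multistarts: int = 8
    fantasy_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if isinstance(self.kappa, str):
            if self.kappa != "auto":
                raise ValidationError(f"kappa must be a number or 'auto', got {self.kappa!r}")
            g = tuple(float(k) for k in self.kappa_grid)
            if not g or any(b <= a for a, b in zip(g, g[1:])):
                raise ValidationError("kappa_grid must be nonempty and strictly ascending")
            self.kappa_grid = g
        elif self.kappa < 0:
            raise ValidationError("kappa must be nonnegative")
        if self.explore_subset_rule not in ("all", "exclude_init", "top_k"):
            raise ValidationError(f"unknown explore_subset_rule {self.explore_subset_rule!r}")
        if self.explore_subset_rule == "top_k" and not self.explore_top_k:
            raise ValidationError("explore_top_k required with rule 'top_k'")


@dataclass(frozen=True)
class Suggestion:
    """A proposed condition, precision-rounded, with its constraint slacks."""

    x: np.ndarray                 # physical units, rounded to device precision
    x_scaled: np.ndarray
    acquisition_value: float
    kappa_used: float
    exploit_slack: float          # normalized Chebyshev metric; feasible iff >= 1
    explore_slack: float          # normalized Manhattan metric; feasible iff <= 1
    feasible: bool


def ucb(fit: GPFit, x, kappa: float):
    """mu_hat + kappa * sigma_hat at one point or a batch of points."""
    if kappa < 0:
        raise ValidationError("kappa must be nonnegative")
    x = np.asarray(x, float)
    single = x.ndim == 1
    mu, sd = fit.predict(np.atleast_2d(x))
    val = mu + kappa * sd
    return float(val[0]) if single else val


def exploit_metric(x, observed, eps) -> float:
    """min_i max_d |x_d - x_id| / eps_d over tested conditions (>= 1 feasible).

    Vacuously +inf when nothing has been observed yet.
    """
    obs = np.atleast_2d(np.asarray(observed, float)) if len(observed) else None
    if obs is None or obs.size == 0:
        return float("inf")
    x = np.asarray(x, float)
    eps = np.asarray(eps, float)
    return float(np.min(np.max(np.abs(obs - x) / eps, axis=1)))


def explore_metric(x, subset, eps) -> float:
    """min_i sum_d |x_d - x_id| / eps_d over the trusted subset (<= 1 feasible)."""
    sub = np.atleast_2d(np.asarray(subset, float)) if len(subset) else None
    if sub is None or sub.size == 0:
        raise EmptySubsetError(
            "exploration subset is empty; widen explore_subset_rule (e.g. 'all')")
    x = np.asarray(x, float)
    eps = np.asarray(eps, float)
    return float(np.min(np.sum(np.abs(sub - x) / eps, axis=1)))


def _finalize(fit: GPFit, space: ParameterSpace, x_scaled: np.ndarray, kappa: float,
              observed, subset) -> Suggestion:
    """Round to device precision, then re-evaluate value and slacks there."""
    x_phys = space.from_scaled(np.clip(x_scaled, 0.0, space.scaled_highs))
    xs = space.to_scaled(x_phys)
    val = ucb(fit, xs, kappa)
    ex = exploit_metric(xs, observed, space.eps_exploit_scaled)
    if subset is None:
        xp = 0.0
        feas_xp = True
    else:
        xp = explore_metric(xs, subset, space.eps_explore_scaled)
        feas_xp = xp <= 1.0 + _FEAS_TOL
    feasible = (ex >= 1.0 - _FEAS_TOL) and feas_xp
    return Suggestion(x=x_phys, x_scaled=xs, acquisition_value=val, kappa_used=float(kappa),
                      exploit_slack=ex, explore_slack=xp, feasible=bool(feasible))


def _starting_points(fit: GPFit, space: ParameterSpace, n: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    highs = space.scaled_highs
    starts = [rng.uniform(0.0, highs) for _ in range(n)]
    starts.append(fit.incumbent.astype(float))
    return starts


def maximize_ucb(
    fit: GPFit,
    kappa: float,
    space: ParameterSpace,
    *,
    observed=None,
    explore_subset=None,
    constraints: bool = True,
    n_multistarts: int = 8,
    rng: Optional[np.random.Generator] = None,
) -> Suggestion:
    """Maximize UCB over the scaled box with SLSQP from multiple starts.

    With ``constraints=True`` the exploitation (>= eps_exploit away from every
    observed point in Chebyshev sense) and, if ``explore_subset`` is given,
    exploration (<= eps_explore from the subset in Manhattan sense)
    constraints are enforced; the best feasible local maximum is returned,
    falling back to the best infeasible point (``feasible=False``) when no
    start lands in the feasible set.  The returned point is rounded to device
    precision and its slacks are re-validated post-rounding.
    """
    rng = np.random.default_rng(rng)
    observed = fit.X if observed is None else np.atleast_2d(np.asarray(observed, float))
    subset = None if explore_subset is None else np.atleast_2d(np.asarray(explore_subset, float))
    if subset is not None and subset.size == 0:
        raise EmptySubsetError(
            "exploration subset is empty; widen explore_subset_rule (e.g. 'all')")
    eps_in = space.eps_exploit_scaled
    eps_out = space.eps_explore_scaled
    bounds = space.scaled_bounds()

    def neg_ucb(x):
        mu, sd = fit.predict(np.atleast_2d(x))
        return float(-(mu[0] + kappa * sd[0]))

    cons = []
    if constraints:
        cons.append({"type": "ineq",
                     "fun": lambda x: exploit_metric(x, observed, eps_in) - 1.0})
        if subset is not None:
            cons.append({"type": "ineq",
                         "fun": lambda x: 1.0 - explore_metric(x, subset, eps_out)})

    candidates: list[tuple[bool, float, np.ndarray]] = []
    n_fail = 0
    for x0 in _starting_points(fit, space, n_multistarts, rng):
        try:
            if constraints and cons:
                res = minimize(neg_ucb, x0, method="SLSQP", bounds=bounds, constraints=cons,
                               options={"maxiter": 200, "ftol": 1e-10})
            else:
                res = minimize(neg_ucb, x0, method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):
            n_fail += 1
            continue
        x = np.clip(np.asarray(res.x, float), 0.0, space.scaled_highs)
        if not np.all(np.isfinite(x)):
            n_fail += 1
            continue
        ok = True
        if constraints:
            ok = exploit_metric(x, observed, eps_in) >= 1.0 - _FEAS_TOL
            if ok and subset is not None:
                ok = explore_metric(x, subset, eps_out) <= 1.0 + _FEAS_TOL
        candidates.append((ok, -neg_ucb(x), x))
    if not candidates:
        raise RuntimeError(
            f"acquisition optimizer failed on all {n_fail} starts (kappa={kappa})")

    def rank(c):
        ok, val, x = c
        # prefer feasible, then higher UCB, then lexicographically smaller point
        return (not ok, -val, tuple(np.round(x, 12)))

    best_ok, _, best_x = sorted(candidates, key=rank)[0]
    sugg = _finalize(fit, space, best_x, kappa, observed, subset)
    if not best_ok and constraints:
        sugg = Suggestion(**{**sugg.__dict__, "feasible": False})
    return sugg


def select_kappa(
    fit: GPFit,
    config: AcquisitionConfig,
    space: ParameterSpace,
    *,
    observed=None,
    explore_subset=None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, Suggestion]:
    """Ascending-grid automatic kappa choice.

    For each kappa on the grid the box-constrained (distance-unconstrained)
    UCB maximizer is computed; the first kappa whose maximizer already
    satisfies both distance constraints is returned with its suggestion.
    If no grid value qualifies, the kappa with the smallest total constraint
    violation is returned, flagged infeasible.
    """
    if not isinstance(config.kappa_grid, tuple) or not config.kappa_grid:
        raise ValidationError("kappa_grid must be a nonempty ascending tuple")
    rng = np.random.default_rng(rng)
    best: Optional[tuple[float, float, Suggestion]] = None
    for kappa in config.kappa_grid:
        sugg = maximize_ucb(fit, kappa, space, observed=observed,
                            explore_subset=explore_subset, constraints=False,
                            n_multistarts=config.n_multistarts, rng=rng)
        if sugg.feasible:
            return float(kappa), sugg
        violation = max(0.0, 1.0 - sugg.exploit_slack) + max(0.0, sugg.explore_slack - 1.0)
        if best is None or violation < best[0]:
            best = (violation, float(kappa), sugg)
    assert best is not None
    return best[1], best[2]


def suggest_batch(
    fit: GPFit,
    config: AcquisitionConfig,
    space: ParameterSpace,
    *,
    observed=None,
    explore_subset=None,
    rng: Optional[np.random.Generator] = None,
) -> list[Suggestion]:
    """Propose ``config.batch_size`` concurrent conditions by fantasy updates.

    Each round obtains one constrained suggestion, then conditions a *copy*
    of the GP on a fantasy observation there whose target is the current
    predictive mean (noise floor ``config.fantasy_floor``); hyperparameters
    are never re-optimized within the batch, and the caller's fit object is
    left untouched, so the fantasies are fully retracted by construction.
    Successive suggestions are mutually exploit-feasible because each fantasy
    joins the observed set for the next round's constraint.
    """
    rng = np.random.default_rng(rng)
    work = fit
    obs = fit.X if observed is None else np.atleast_2d(np.asarray(observed, float))
    subset = None if explore_subset is None else np.atleast_2d(np.asarray(explore_subset, float))
    out: list[Suggestion] = []
    for _ in range(config.batch_size):
        if config.kappa == "auto":
            _, sugg = select_kappa(work, config, space, observed=obs,
                                   explore_subset=subset, rng=rng)
        else:
            sugg = maximize_ucb(work, float(config.kappa), space, observed=obs,
                                explore_subset=subset, constraints=True,
                                n_multistarts=config.n_multistarts, rng=rng)
        out.append(sugg)
        fantasy_y, _ = work.predict_one(sugg.x_scaled)
        work = work.with_observation(sugg.x_scaled, fantasy_y, config.fantasy_floor)
        obs = np.vstack([obs, sugg.x_scaled])
        if subset is not None:
            subset = np.vstack([subset, sugg.x_scaled])
    return out
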