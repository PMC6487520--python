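"""Human-in-the-loop session: ledger persistence and the observe/suggest cycle.

A :class:`Session` couples an :class:`~seedbo.config.ExperimentConfig` with a
trial ledger.  The operator cycle is: ``initialize`` (corner pseudo-points),
``ingest_observation`` after each germination run, ``suggest`` for the next
batch of chamber settings, ``report`` for progress.  Fantasy observations
used inside batch suggestion never reach the ledger; suggestions can be
parked as *pending* rows (provenance "bo", empty counts) and are completed by
the matching ``ingest_observation`` call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acquisition import EmptySubsetError, Suggestion, suggest_batch
from .config import ExperimentConfig
from .germination_score import (GerminationCount, append_ledger_row, efficiency_percent,
                                empty_ledger, noise_floor_for, read_ledger,
                                round_half_up, target_score, write_ledger)
from .gp_model import GPFit, fit_mle
from .parameter_space import ParameterVector, ValidationError, corner_init_points

__all__ = ["Session"]

log = logging.getLogger("seedbo")


@dataclass
class Session:
    config: ExperimentConfig
    ledger: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    fit: Optional[GPFit] = None

    def __post_init__(self) -> None:
        if self.ledger is None:
            self.ledger = empty_ledger(self.config.space)
        self._rng_fit = np.random.default_rng(
            np.random.SeedSequence([self.config.seed, 1]))
        self._rng_acq = np.random.default_rng(
            np.random.SeedSequence([self.config.seed, 2]))

    # -- construction / persistence -----------------------------------------

    @classmethod
    def from_files(cls, config_path, ledger_path=None) -> "Session":
        config = ExperimentConfig.load(config_path)
        ledger = None
        if ledger_path is not None and Path(ledger_path).exists():
            ledger = read_ledger(ledger_path, config.space)
        return cls(config, ledger)

    def save_ledger(self, path) -> None:
        write_ledger(self.ledger, path)

    # -- data ingestion ------------------------------------------------------

    def initialize(self) -> int:
        """Add the corner pseudo-observations (temperature extremes, score 0)."""
        space = self.config.space
        binary = [p.name for p in space.params if p.unit == "degC"]
        fixed = [p.name for p in space.params if p.unit != "degC"]
        points = corner_init_points(space, binary, fixed)
        for i, (pt, target) in enumerate(points):
            self.ledger = append_ledger_row(
                self.ledger, space, trial_id="init", chamber_id=f"c{i:02d}",
                provenance="init", x_physical=np.asarray(pt), y=target,
                noise_floor=noise_floor_for(target, self.config.seeds_per_trial,
                                            self.config.noise_mode))
        self.fit = None
        log.info("initialized with %d corner points", len(points))
        return len(points)

    def _pending_index(self, trial_id: str, chamber_id: str) -> Optional[int]:
        m = (self.ledger["trial_id"] == trial_id) & (self.ledger["chamber_id"] == chamber_id)
        if not m.any():
            return None
        idx = int(np.flatnonzero(m)[0])
        if pd.isna(self.ledger.loc[idx, "y"]):
            return idx
        raise ValidationError(
            f"duplicate observation for trial={trial_id!r} chamber={chamber_id!r}")

    def ingest_observation(self, trial_id: str, chamber_id: str,
                           x: Sequence[float] | ParameterVector,
                           count: GerminationCount,
                           provenance: str = "expert",
                           timestamp: str = "") -> float:
        """Record a germination outcome; returns the score y.

        If a pending suggestion row with the same ids exists it is completed
        in place; otherwise a new row is appended.  A second result for the
        same (trial, chamber) is rejected.
        """
        space = self.config.space
        xv = np.asarray(x if not isinstance(x, ParameterVector) else np.asarray(x), float)
        y = target_score(count)
        floor = noise_floor_for(y, count.n_seeds, self.config.noise_mode)
        pending = self._pending_index(trial_id, chamber_id)
        if pending is not None:
            space.validate(xv)
            self.ledger.loc[pending, list(space.names)] = xv
            self.ledger.loc[pending, ["N", "N_g", "N_wg", "y", "noise_floor", "timestamp"]] = [
                count.n_seeds, count.n_germinated, count.n_well, y, floor, timestamp]
        else:
            self.ledger = append_ledger_row(
                self.ledger, space, trial_id=trial_id, chamber_id=chamber_id,
                provenance=provenance, x_physical=xv, count=count,
                noise_floor=floor, timestamp=timestamp)
        self.fit = None   # hyperparameters are re-optimized when real data arrives
        log.info("observed trial=%s chamber=%s y=%.3f", trial_id, chamber_id, y)
        return y

    # -- modeling / suggestion ----------------------------------------------

    @property
    def _scored(self) -> pd.DataFrame:
        return self.ledger[~self.ledger["y"].isna()]

    def refit(self) -> GPFit:
        df = self._scored
        X = df[list(self.config.space.names)].to_numpy(float)
        Xs = np.array([self.config.space.to_scaled(row) for row in X])
        y = df["y"].to_numpy(float)
        floors = (df["noise_floor"].to_numpy(float)
                  if self.config.noise_mode == "per_obs" else None)
        self.fit = fit_mle(Xs, y, floors=floors, bounds=self.config.kernel_bounds(),
                           n_restarts=self.config.n_restarts, rng=self._rng_fit)
        h = self.fit.hyperparams
        log.info("refit: alpha=%.4g rho=%.4g sigma2=%.4g lml=%.3f",
                 h.amplitude, h.length_scale, h.noise, self.fit.log_marginal_likelihood)
        return self.fit

    def _explore_subset(self, Xs: np.ndarray, df: pd.DataFrame) -> np.ndarray:
        rule = self.config.explore_subset_rule
        if rule == "all":
            sub = Xs
        elif rule == "exclude_init":
            sub = Xs[(df["provenance"] != "init").to_numpy()]
        else:  # top_k
            order = np.argsort(df["y"].to_numpy(float))[::-1][: self.config.explore_top_k]
            sub = Xs[order]
        if sub.size == 0:
            raise EmptySubsetError(
                f"explore subset empty under rule {rule!r}; observe real data first "
                "or set explore_subset_rule='all'")
        return sub

    def suggest(self, batch_size: Optional[int] = None,
                kappa: Optional[float | str] = None,
                constraints: bool = True,
                append_pending: bool = False) -> list[Suggestion]:
        """Fit (if stale) and propose the next batch of chamber settings."""
        if self.fit is None:
            self.refit()
        df = self._scored
        Xs = np.array([self.config.space.to_scaled(row)
                       for row in df[list(self.config.space.names)].to_numpy(float)])
        acq = self.config.acquisition_config()
        if batch_size is not None:
            acq.batch_size = int(batch_size)
        if kappa is not None:
            acq.kappa = kappa if kappa == "auto" else float(kappa)
        subset = self._explore_subset(Xs, df) if constraints else None
        suggestions = suggest_batch(self.fit, acq, self.config.space,
                                    observed=Xs if constraints else Xs,
                                    explore_subset=subset, rng=self._rng_acq)
        for s in suggestions:
            log.info("suggest kappa=%.2f ucb=%.3f exploit=%.2f explore=%.2f feasible=%s",
                     s.kappa_used, s.acquisition_value, s.exploit_slack,
                     s.explore_slack, s.feasible)
        if append_pending:
            trial = f"t{self._next_trial_number():02d}"
            for c, s in enumerate(suggestions, start=1):
                self.ledger = append_ledger_row(
                    self.ledger, self.config.space, trial_id=trial,
                    chamber_id=f"c{c}", provenance="bo", x_physical=s.x)
        return suggestions

    def _next_trial_number(self) -> int:
        nums = [int(t[1:]) for t in self.ledger["trial_id"].unique()
                if isinstance(t, str) and t.startswith("t") and t[1:].isdigit()]
        return (max(nums) + 1) if nums else 1

    # -- reporting -----------------------------------------------------------

    def report(self) -> dict:
        """Progress summary: per-trial scores, best-so-far, efficiencies.

        Efficiency is the score as a percent of the metric maximum 2 (one
        decimal); improvement is (y_best - y_init)/y_init * 100 rounded to
        the nearest integer, with the first expert observation as baseline.
        """
        df = self._scored
        real = df[df["provenance"] != "init"]
        if df.empty:
            raise ValidationError("ledger holds no scored observations")
        per_trial = [
            {"trial_id": t, "best": float(g["y"].max()), "mean": float(g["y"].mean())}
            for t, g in real.groupby("trial_id", sort=False)
        ]
        out: dict = {
            "n_observations": int(len(df)),
            "n_real": int(len(real)),
            "per_trial": per_trial,
            "best_so_far": list(np.maximum.accumulate(real["y"].to_numpy(float)))
            if len(real) else [],
        }
        if len(real) == 0:
            out["warning"] = "no real observations yet; summary is partial"
            return out
        best_y = float(real["y"].max())
        out["best_y"] = best_y
        best_row = real.loc[real["y"].idxmax()]
        out["best_x"] = {n: float(best_row[n]) for n in self.config.space.names}
        out["best_efficiency_percent"] = round_half_up(efficiency_percent(best_y), 1)
        expert = real[real["provenance"] == "expert"]
        if len(expert):
            y0 = float(expert.iloc[0]["y"])
            out["initial_y"] = y0
            out["initial_efficiency_percent"] = round_half_up(efficiency_percent(y0), 1)
            if y0 > 0:
                out["improvement_percent"] = int(round_half_up((best_y - y0) / y0 * 100, 0))
        else:
            out["warning"] = "no expert baseline row; improvement not computed"
        return out
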