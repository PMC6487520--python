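"""Germination target score, its Bernoulli noise model, and the trial ledger.

A trial places ``N`` seeds under one condition and counts ``N_g`` germinated
seeds (radicle emerged; this count *includes* the well-germinated ones) and
``N_wg`` well-germinated seeds (a stricter criterion).  The optimized score is

    y = (N_g + N_wg) / N,   y in [0, 2],

so a well-germinated seed is worth two points and a merely germinated one a
single point.  Modeling a single seed as a two-stage Bernoulli trial --
germinate with probability p, then well-germinate with probability q -- gives

    E[y]   = mu      = p (1 + q)
    N*Var[y] = sigma^2 = p (1 + 3q) - p^2 (1 + q)^2,

a normal approximation valid for large N.  The variance is bounded by 1
(attained at p = 1/2, q = 1), yielding the global observation-noise floor
1/N; conditioning on the observed score tightens it to y (2 - y) / N per
observation.  Both floors are exposed here and consumed by the GP model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameter_space import ParameterSpace, ValidationError

__all__ = [
    "SCORE_MAX",
    "PROVENANCE_TAGS",
    "CountConsistencyError",
    "GerminationCount",
    "Observation",
    "target_score",
    "efficiency_percent",
    "round_half_up",
    "model_mean",
    "model_variance",
    "variance_floor_global",
    "variance_floor_per_obs",
    "noise_floor_for",
    "ledger_columns",
    "empty_ledger",
    "append_ledger_row",
    "validate_ledger",
    "read_ledger",
    "write_ledger",
]

SCORE_MAX = 2.0
PROVENANCE_TAGS = ("init", "expert", "bo", "fantasy")


class CountConsistencyError(ValueError):
    """Germination counts violate 0 <= N_wg <= N_g <= N."""


@dataclass(frozen=True)
class GerminationCount:
    """Raw outcome of one germination run.

    ``n_germinated`` counts every seed with an emerged radicle, *including*
    the well-germinated ones, so ``n_well <= n_germinated <= n_seeds``.
    """

    n_seeds: int
    n_germinated: int
    n_well: int

    def __post_init__(self) -> None:
        for f in ("n_seeds", "n_germinated", "n_well"):
            v = getattr(self, f)
            if int(v) != v:
                raise CountConsistencyError(f"{f} must be an integer, got {v}")
            object.__setattr__(self, f, int(v))
        if self.n_seeds < 1:
            raise CountConsistencyError("n_seeds must be >= 1")
        if not (0 <= self.n_well <= self.n_germinated <= self.n_seeds):
            raise CountConsistencyError(
                f"need 0 <= N_wg <= N_g <= N, got N={self.n_seeds}, "
                f"N_g={self.n_germinated}, N_wg={self.n_well}"
            )


@dataclass(frozen=True)
class Observation:
    """One scored data point: scaled location, target y, and its noise floor."""

    x_scaled: tuple[float, ...]
    y: float
    noise_floor: float
    provenance: str
    trial_id: str = ""
    chamber_id: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE_TAGS:
            raise ValidationError(
                f"provenance {self.provenance!r} not in {PROVENANCE_TAGS}")
        if not (-1e-12 <= self.y <= SCORE_MAX + 1e-12):
            raise ValidationError(f"target y={self.y} outside [0, {SCORE_MAX}]")
        if self.noise_floor < 0:
            raise ValidationError("noise_floor must be nonnegative")
        object.__setattr__(self, "x_scaled", tuple(float(v) for v in self.x_scaled))


# -- score arithmetic --------------------------------------------------------


def target_score(count: GerminationCount) -> float:
    """(N_g + N_wg) / N, in [0, 2]."""
    return (count.n_germinated + count.n_well) / count.n_seeds


def efficiency_percent(y: float) -> float:
    """Score expressed as a percentage of the metric maximum 2."""
    if not (-1e-12 <= y <= SCORE_MAX + 1e-12):
        raise ValidationError(f"score {y} outside [0, {SCORE_MAX}]")
    return y / SCORE_MAX * 100.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed percentages conventionally are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# -- two-stage Bernoulli moments --------------------------------------------


def _check_unit(name: str, v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValidationError(f"{name} must lie in [0, 1]")
    return a


def model_mean(p, q):
    """E[y] = p (1 + q) for single-seed germination/well-germination probabilities."""
    p = _check_unit("p", p)
    q = _check_unit("q", q)
    out = p * (1.0 + q)
    return float(out) if out.ndim == 0 else out


def model_variance(p, q):
    """Single-seed score variance sigma^2 = p (1 + 3q) - p^2 (1 + q)^2."""
    p = _check_unit("p", p)
    q = _check_unit("q", q)
    out = p * (1.0 + 3.0 * q) - p**2 * (1.0 + q) ** 2
    return float(out) if out.ndim == 0 else out


def variance_floor_global(n_seeds: int) -> float:
    """Global noise-variance floor 1/N (the maximum of sigma^2 over p, q is 1)."""
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    return 1.0 / n_seeds


def variance_floor_per_obs(y: float, n_seeds: int) -> float:
    """Observation-conditional floor y (2 - y) / N.

    This is the supremum of sigma^2/N over all (p, q) whose mean p(1+q)
    equals the observed score: mu(2-mu) - sigma^2 = p(1-q) >= 0.
    """
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    if not (-1e-12 <= y <= SCORE_MAX + 1e-12):
        raise ValidationError(f"score {y} outside [0, {SCORE_MAX}]")
    return y * (SCORE_MAX - y) / n_seeds


def noise_floor_for(y: float, n_seeds: int, mode: str) -> float:
    """Noise floor recorded for an observation under the configured mode."""
    if mode == "global":
        return variance_floor_global(n_seeds)
    if mode == "per_obs":
        return variance_floor_per_obs(y, n_seeds)
    raise ValidationError(f"unknown noise mode {mode!r} (use 'global' or 'per_obs')")


# -- trial ledger ------------------------------------------------------------
#
# One CSV row per germination run.  Parameter columns hold physical units;
# counts may be empty for pseudo-rows (corner init) and for provisional
# suggestions awaiting lab results.  Fantasy points never reach the ledger.

_HEAD = ["trial_id", "chamber_id", "provenance"]
_TAIL = ["N", "N_g", "N_wg", "y", "noise_floor", "timestamp"]


def ledger_columns(space: ParameterSpace) -> list[str]:
    return _HEAD + list(space.names) + _TAIL


def empty_ledger(space: ParameterSpace) -> pd.DataFrame:
    return pd.DataFrame(columns=ledger_columns(space))


def append_ledger_row(
    ledger: pd.DataFrame,
    space: ParameterSpace,
    *,
    trial_id: str,
    chamber_id: str,
    provenance: str,
    x_physical: Sequence[float],
    count: Optional[GerminationCount] = None,
    y: Optional[float] = None,
    noise_floor: Optional[float] = None,
    timestamp: str = "",
) -> pd.DataFrame:
    """Return the ledger with one validated row appended (input left untouched)."""
    if provenance == "fantasy":
        raise ValidationError("fantasy observations are never persisted to the ledger")
    if provenance not in PROVENANCE_TAGS:
        raise ValidationError(f"provenance {provenance!r} not in {PROVENANCE_TAGS}")
    x = space.validate(x_physical)
    row: dict = {"trial_id": trial_id, "chamber_id": chamber_id, "provenance": provenance}
    row.update(dict(zip(space.names, x)))
    if count is not None:
        ytrue = target_score(count)
        if y is not None and abs(y - ytrue) > 1e-9:
            raise ValidationError(f"y={y} inconsistent with counts (expect {ytrue})")
        y = ytrue
        row.update({"N": count.n_seeds, "N_g": count.n_germinated, "N_wg": count.n_well})
    else:
        row.update({"N": np.nan, "N_g": np.nan, "N_wg": np.nan})
    row["y"] = np.nan if y is None else float(y)
    row["noise_floor"] = np.nan if noise_floor is None else float(noise_floor)
    row["timestamp"] = timestamp
    new = pd.DataFrame([row])
    if len(ledger) == 0:
        out = new
    else:
        out = pd.concat([ledger, new], ignore_index=True)
    return out[ledger_columns(space)]


def validate_ledger(ledger: pd.DataFrame, space: ParameterSpace) -> None:
    """Check column layout, bounds, provenance tags and count consistency."""
    cols = ledger_columns(space)
    if list(ledger.columns) != cols:
        raise ValidationError(f"ledger columns {list(ledger.columns)} != expected {cols}")
    for _, row in ledger.iterrows():
        if row["provenance"] not in ("init", "expert", "bo"):
            raise ValidationError(f"ledger provenance {row['provenance']!r} invalid")
        space.validate([row[n] for n in space.names])
        has_counts = not pd.isna(row["N"])
        if has_counts:
            c = GerminationCount(int(row["N"]), int(row["N_g"]), int(row["N_wg"]))
            if abs(target_score(c) - float(row["y"])) > 1e-9:
                raise ValidationError(
                    f"row {row['trial_id']}/{row['chamber_id']}: y inconsistent with counts")
        if not pd.isna(row["y"]) and not (-1e-12 <= row["y"] <= SCORE_MAX + 1e-12):
            raise ValidationError(f"ledger y={row['y']} outside [0, {SCORE_MAX}]")


def write_ledger(ledger: pd.DataFrame, path) -> None:
    Path(path).write_text(ledger_to_csv(ledger))


def ledger_to_csv(ledger: pd.DataFrame) -> str:
    buf = io.StringIO()
    ledger.to_csv(buf, index=False)
    return buf.getvalue()


def read_ledger(path, space: ParameterSpace) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trial_id": str, "chamber_id": str, "timestamp": str})
    df["trial_id"] = df["trial_id"].fillna("")
    df["chamber_id"] = df["chamber_id"].fillna("")
    df["timestamp"] = df["timestamp"].fillna("")
    validate_ledger(df, space)
    return df
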