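"""Controllable-condition parameter space and coordinate transforms.

A germination experiment exposes a handful of chamber set-points: air
temperatures on successive time steps and amounts of water supplied at fixed
times.  Each parameter has physical bounds (e.g. 0--40 degC, 0--250 ml) and is
mapped linearly onto a scaled interval ``[0, scaled_high]`` so that an
isotropic kernel sees commensurate coordinates.  With temperature mapped to
[0, 1] and water to [0, 0.5], a 1 degC step and a 12.5 ml step produce the
same scaled displacement (0.025), i.e. the two units are treated as
equivalent at that exchange rate.

Vectors are positional against an ordered :class:`ParameterSpace`; the order
is fixed for the lifetime of a session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ParameterDef",
    "ParameterSpace",
    "ParameterVector",
    "corner_init_points",
    "pea_space",
    "radish_space",
    "single_temperature_space",
]


class ValidationError(ValueError):
    """A value or configuration violates a declared invariant."""


@dataclass(frozen=True)
class ParameterDef:
    """One controllable set-point (a temperature or a water amount).

    Parameters
    ----------
    name, unit:
        Identifier and physical unit ("degC" or "ml").
    low, high:
        Physical bounds of the set-point.
    scaled_high:
        Upper end of the scaled interval the physical range maps onto
        (1.0 for temperature, 0.5 for water in the default configuration).
    eps_exploit:
        Exploitation threshold in physical units: a new suggestion must move
        at least this far from every tested condition in at least one
        coordinate (chamber resolution sets the natural value, 0.1 degC / 1 ml).
    eps_explore:
        Exploration threshold in physical units: a suggestion may wander at
        most this far, in total, from the nearest trusted condition
        (10 degC / 100 ml by default).
    precision:
        Device rounding step; suggestions are reported rounded to it.
    """

    name: str
    unit: str
    low: float
    high: float
    scaled_high: float = 1.0
    eps_exploit: float = 0.1
    eps_explore: float = 10.0
    precision: float = 0.1

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"{self.name}: low ({self.low}) must be < high ({self.high})")
        if self.scaled_high <= 0:
            raise ValidationError(f"{self.name}: scaled_high must be positive")
        if not (0 < self.eps_exploit < self.eps_explore <= self.high - self.low):
            raise ValidationError(
                f"{self.name}: need 0 < eps_exploit < eps_explore <= high - low, "
                f"got eps_exploit={self.eps_exploit}, eps_explore={self.eps_explore}"
            )
        if self.precision <= 0:
            raise ValidationError(f"{self.name}: precision must be positive")

    @property
    def span(self) -> float:
        return self.high - self.low

    def scale(self, value: float) -> float:
        """Physical value -> scaled coordinate in [0, scaled_high]."""
        return (value - self.low) / self.span * self.scaled_high

    def unscale(self, s: float) -> float:
        """Scaled coordinate -> physical value (no precision rounding)."""
        return self.low + s / self.scaled_high * self.span

    @property
    def eps_exploit_scaled(self) -> float:
        return self.eps_exploit / self.span * self.scaled_high

    @property
    def eps_explore_scaled(self) -> float:
        return self.eps_explore / self.span * self.scaled_high


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of :class:`ParameterDef`; coordinates are positional."""

    params: tuple[ParameterDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(self.params))
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValidationError("parameter names must be unique")
        if not self.params:
            raise ValidationError("parameter space must hold at least one parameter")

    # -- basic introspection -------------------------------------------------

    @property
    def dim(self) -> int:
        return len(self.params)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    def __getitem__(self, name: str) -> ParameterDef:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    # -- transforms ----------------------------------------------------------

    def validate(self, values: Sequence[float]) -> np.ndarray:
        """Check a physical vector against bounds; error names the parameter."""
        v = np.asarray(values, dtype=float)
        if v.shape != (self.dim,):
            raise ValidationError(f"expected {self.dim} values, got shape {v.shape}")
        for p, x in zip(self.params, v):
            if not (p.low - 1e-12 <= x <= p.high + 1e-12):
                raise ValidationError(
                    f"{p.name}={x} outside physical bounds [{p.low}, {p.high}] {p.unit}"
                )
        return v

    def to_scaled(self, values: Sequence[float]) -> np.ndarray:
        """Physical vector -> scaled vector (coordinate d in [0, scaled_high_d])."""
        v = self.validate(values)
        return np.array([p.scale(x) for p, x in zip(self.params, v)])

    def from_scaled(self, scaled: Sequence[float], round_to_precision: bool = True) -> np.ndarray:
        """Scaled vector -> physical vector, optionally rounded to device precision."""
        s = np.asarray(scaled, dtype=float)
        if s.shape != (self.dim,):
            raise ValidationError(f"expected {self.dim} scaled values, got shape {s.shape}")
        for p, x in zip(self.params, s):
            if not (-1e-9 <= x <= p.scaled_high + 1e-9):
                raise ValidationError(
                    f"{p.name}: scaled value {x} outside [0, {p.scaled_high}]"
                )
        v = np.array([p.unscale(x) for p, x in zip(self.params, s)])
        if round_to_precision:
            v = self.round_to_precision(v)
        return v

    def round_to_precision(self, values: Sequence[float]) -> np.ndarray:
        """Snap a physical vector to each parameter's device step, clipped to bounds."""
        v = np.asarray(values, dtype=float)
        out = np.empty_like(v)
        for i, (p, x) in enumerate(zip(self.params, v)):
            r = np.round(x / p.precision) * p.precision
            # kill float dust like 24.700000000000003 so ledgers print cleanly
            out[i] = min(max(round(r, 10), p.low), p.high)
        return out

    # -- scaled-space geometry ----------------------------------------------

    def scaled_bounds(self) -> list[tuple[float, float]]:
        return [(0.0, p.scaled_high) for p in self.params]

    @property
    def scaled_highs(self) -> np.ndarray:
        return np.array([p.scaled_high for p in self.params])

    @property
    def eps_exploit_scaled(self) -> np.ndarray:
        return np.array([p.eps_exploit_scaled for p in self.params])

    @property
    def eps_explore_scaled(self) -> np.ndarray:
        return np.array([p.eps_explore_scaled for p in self.params])


@dataclass(frozen=True)
class ParameterVector:
    """A validated point in physical units, tied to its space."""

    values: tuple[float, ...]
    space: ParameterSpace

    def __post_init__(self) -> None:
        v = self.space.validate(self.values)
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @property
    def scaled(self) -> np.ndarray:
        return self.space.to_scaled(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.space.names, self.values))

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.array(self.values, dtype=dtype or float)


def corner_init_points(
    space: ParameterSpace,
    binary_dims: Iterable[str],
    fixed_zero_dims: Iterable[str],
) -> list[tuple[ParameterVector, float]]:
    """Box-vertex initialization points, each carrying a pseudo-target of 0.

    Extreme conditions germinate nothing, so every combination of {low, high}
    over ``binary_dims`` (with ``fixed_zero_dims`` pinned at 0) is entered as
    an "observed" score of 0 to kick the optimizer off without lab work.
    Returns ``2**len(binary_dims)`` points.
    """
    binary = list(binary_dims)
    fixed = list(fixed_zero_dims)
    names = set(space.names)
    if set(binary) | set(fixed) != names or set(binary) & set(fixed):
        raise ValidationError(
            "binary_dims and fixed_zero_dims must partition the parameter space"
        )
    if not binary:
        warnings.warn("no binary dims given; emitting a single all-zero init point")
    choices: dict[str, tuple[float, ...]] = {}
    for p in space.params:
        if p.name in binary:
            choices[p.name] = (p.low, p.high)
        else:
            if not (p.low <= 0.0 <= p.high):
                raise ValidationError(f"{p.name}: 0 is outside bounds, cannot pin at zero")
            choices[p.name] = (0.0,)
    points: list[tuple[ParameterVector, float]] = []
    counters = [0] * space.dim
    sizes = [len(choices[p.name]) for p in space.params]
    while True:
        vals = tuple(choices[p.name][c] for p, c in zip(space.params, counters))
        points.append((ParameterVector(vals, space), 0.0))
        # odometer increment over the per-dimension choices
        i = space.dim - 1
        while i >= 0:
            counters[i] += 1
            if counters[i] < sizes[i]:
                break
            counters[i] = 0
            i -= 1
        if i < 0:
            break
    return points


# -- stock spaces ------------------------------------------------------------


def _temp(name: str) -> ParameterDef:
    return ParameterDef(name, "degC", 0.0, 40.0, scaled_high=1.0,
                        eps_exploit=0.1, eps_explore=10.0, precision=0.1)


def _water(name: str) -> ParameterDef:
    return ParameterDef(name, "ml", 0.0, 250.0, scaled_high=0.5,
                        eps_exploit=1.0, eps_explore=100.0, precision=1.0)


def pea_space() -> ParameterSpace:
    """7-D space of the pea protocol: temperatures t1..t4, water amounts w1..w3."""
    return ParameterSpace(tuple([_temp(f"t{i}") for i in range(1, 5)]
                                + [_water(f"w{i}") for i in range(1, 4)]))


def radish_space() -> ParameterSpace:
    """4-D temperature-only space of the radish protocol (t1..t4)."""
    return ParameterSpace(tuple(_temp(f"t{i}") for i in range(1, 5)))


def single_temperature_space() -> ParameterSpace:
    """1-D toy space (a single temperature) for oracle tests and demos."""
    return ParameterSpace((_temp("t1"),))
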