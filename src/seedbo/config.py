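"""Experiment configuration: parameter space, noise mode, kernel bounds, seeds.

Loadable from YAML or JSON.  The document mirrors the dataclass fields, with
``parameters:`` holding one mapping per controllable set-point, e.g.::

    parameters:
      - {name: t1, unit: degC, low: 0, high: 40, scaled_high: 1.0,
         eps_exploit: 0.1, eps_explore: 10, precision: 0.1}
    seeds_per_trial: 100
    batch_size: 3
    kappa: auto
    noise_mode: global
    n_restarts: 30
    seed: 0
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .acquisition import AcquisitionConfig, _default_grid
from .germination_score import variance_floor_global
from .parameter_space import (ParameterDef, ParameterSpace, ValidationError,
                              pea_space, radish_space, single_temperature_space)

__all__ = ["ExperimentConfig", "pea_config", "radish_config", "unimodal_config"]


@dataclass
class ExperimentConfig:
    space: ParameterSpace
    seeds_per_trial: int = 100
    batch_size: int = 3
    kappa: float | str = "auto"
    kappa_grid: tuple[float, ...] = field(default_factory=_default_grid)
    noise_mode: str = "global"          # "global" (1/N bound) or "per_obs" (y(2-y)/N)
    amplitude_bounds: tuple[float, float] = (1e-5, 1e5)
    length_scale_bounds: tuple[float, float] = (1e-5, 1e5)
    noise_bounds: Optional[tuple[float, float]] = None   # default (1/N, 1e5)
    n_restarts: int = 30
    n_multistarts: int = 8
    explore_subset_rule: str = "exclude_init"
    explore_top_k: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seeds_per_trial < 1:
            raise ValidationError("seeds_per_trial must be >= 1")
        if self.noise_mode not in ("global", "per_obs"):
            raise ValidationError(f"unknown noise_mode {self.noise_mode!r}")
        self.kappa_grid = tuple(float(k) for k in self.kappa_grid)

    @property
    def resolved_noise_bounds(self) -> tuple[float, float]:
        """White-noise box; the lower end defaults to the 1/N germination floor."""
        if self.noise_bounds is not None:
            return tuple(self.noise_bounds)
        return (variance_floor_global(self.seeds_per_trial), 1e5)

    def kernel_bounds(self) -> tuple[tuple[float, float], ...]:
        return (tuple(self.amplitude_bounds), tuple(self.length_scale_bounds),
                self.resolved_noise_bounds)

    def acquisition_config(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            kappa=self.kappa,
            kappa_grid=self.kappa_grid,
            batch_size=self.batch_size,
            explore_subset_rule=self.explore_subset_rule,
            explore_top_k=self.explore_top_k,
            n_multistarts=self.n_multistarts,
            fantasy_floor=variance_floor_global(self.seeds_per_trial),
        )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["parameters"] = [asdict(p) for p in self.space.params]
        del d["space"]
        d["kappa_grid"] = list(self.kappa_grid)
        for k in ("amplitude_bounds", "length_scale_bounds"):
            d[k] = list(d[k])
        if d["noise_bounds"] is not None:
            d["noise_bounds"] = list(d["noise_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        params = tuple(ParameterDef(**p) for p in d.pop("parameters"))
        for k in ("kappa_grid", "amplitude_bounds", "length_scale_bounds", "noise_bounds"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(space=ParameterSpace(params), **d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(doc)


def pea_config(**overrides) -> ExperimentConfig:
    """7-parameter pea protocol: N=100 seeds, 3 chambers per trial."""
    kw: dict = dict(space=pea_space(), seeds_per_trial=100, batch_size=3)
    kw.update(overrides)
    return ExperimentConfig(**kw)


def radish_config(**overrides) -> ExperimentConfig:
    """4-temperature radish protocol: N=96 seeds, 6 repetitions per trial."""
    kw: dict = dict(space=radish_space(), seeds_per_trial=96, batch_size=1)
    kw.update(overrides)
    return ExperimentConfig(**kw)


def unimodal_config(**overrides) -> ExperimentConfig:
    """1-D toy protocol for oracle tests."""
    kw: dict = dict(space=single_temperature_space(), seeds_per_trial=100, batch_size=1)
    kw.update(overrides)
    return ExperimentConfig(**kw)
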