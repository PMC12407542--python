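"""Run configuration: serializable description of one reproducible run."""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .parameters import (
    ModelVariant,
    Parameters,
    ValidationError,
    make_parameters,
)


@dataclass(frozen=True)
class DoseGridSpec:
    """Log- or linear-spaced drug dose grid (µM)."""

    dose_min: float = 1e-4
    dose_max: float = 1e2
    n: int = 121
    log: bool = True

    def values(self) -> np.ndarray:
        if self.dose_min <= 0 and self.log:
            raise ValidationError("log dose grid requires dose_min > 0")
        if self.n < 2 or self.dose_max <= self.dose_min:
            raise ValidationError("dose grid needs n >= 2 and dose_max > dose_min")
        if self.log:
            return np.logspace(np.log10(self.dose_min), np.log10(self.dose_max), self.n)
        return np.linspace(self.dose_min, self.dose_max, self.n)


@dataclass(frozen=True)
class AxisSpec:
    """One log-spaced sweep axis: a Parameters field name or ``alpha``."""

    name: str
    lo: float
    hi: float
    n: int

    def values(self) -> np.ndarray:
        if self.lo <= 0 or self.hi <= self.lo or self.n < 1:
            raise ValidationError(f"bad axis spec for {self.name!r}")
        if self.n == 1:
            return np.array([self.lo])
        return np.logspace(np.log10(self.lo), np.log10(self.hi), self.n)


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; embedded in every output's JSON sidecar."""

    parameters: Parameters = field(default_factory=Parameters.defaults)
    variant: ModelVariant = ModelVariant.CAS_DS
    engine: str = "oracle"
    mode: str = "total_drug"
    dose_grid: DoseGridSpec = field(default_factory=DoseGridSpec)
    sweep_metric: str = "crossover_dose"
    sweep_axes: tuple[AxisSpec, ...] = ()
    grid_n: int = 11
    outdir: str = "."
    seed: int = 0
    verbosity: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["variant"] = self.variant.value
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        if "parameters" in data:
            kwargs["parameters"] = make_parameters(data.pop("parameters"))
        if "variant" in data:
            kwargs["variant"] = ModelVariant(data.pop("variant"))
        if "dose_grid" in data:
            kwargs["dose_grid"] = DoseGridSpec(**data.pop("dose_grid"))
        if "sweep_axes" in data:
            kwargs["sweep_axes"] = tuple(AxisSpec(**a) for a in data.pop("sweep_axes"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "RunConfig":
        path = pathlib.Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValidationError(f"{path}: expected a mapping")
        return cls.from_dict(data)


def write_sidecar(csv_path: pathlib.Path, config: RunConfig) -> pathlib.Path:
    """Write the resolved config + package version next to an output CSV."""
    from . import __version__

    sidecar = csv_path.with_suffix(".json")
    payload = {"config": config.to_dict(), "version": __version__, "output": csv_path.name}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar
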