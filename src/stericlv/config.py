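"""Run configuration: schema, defaults, and YAML/TOML loading.

All defaults equal the standard simulation conditions: Δt = 0.01,
equilibrium tolerance 0.001, 5000-doubling-time cap, 0.2% seeding,
5/1.29 pixels per λ, ⟨P⟩ = 0.25, R = 3, dx/R = 3.5, L = 150, δ = 0.
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .environment import PIXELS_PER_LAMBDA
from .interactions import validate_sampling_spec

SCHEMA_VERSION = "1"


class ConfigError(ValueError):
    pass


@dataclass
class EnvironmentConfig:
    L: float = 150.0
    R: float = 3.0
    dx_over_R: float = 3.5
    delta: float = 0.0
    pixels_per_lambda: float = PIXELS_PER_LAMBDA

    @property
    def dx(self) -> float:
        return self.dx_over_R * self.R


@dataclass
class SamplingConfig:
    N: int = 8
    mean_p: float = 0.25
    delta_p: float = 0.0


@dataclass
class SimulationSection:
    dt: float = 0.01
    sigma: float | None = None
    seeding_fraction: float = 0.002
    max_time: float = 5000.0
    equilibrium_tol: float = 0.001
    record_interval: int = 100


@dataclass
class SeedsConfig:
    env: int = 0
    matrix: int = 0
    init: int = 0


@dataclass
class RunConfig:
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    seeds: SeedsConfig = field(default_factory=SeedsConfig)
    schema_version: str = SCHEMA_VERSION

    def validate(self) -> "RunConfig":
        e, s, sim = self.environment, self.sampling, self.simulation
        if e.dx <= 2 * e.R:
            raise ConfigError(
                f"environment.dx_over_R: dx={e.dx} must exceed 2R={2 * e.R}")
        if e.L <= e.dx:
            raise ConfigError("environment.L: must exceed lattice spacing")
        if e.delta < 0:
            raise ConfigError("environment.delta: must be >= 0")
        try:
            validate_sampling_spec(s.N, s.mean_p, s.delta_p)
        except ValueError as exc:
            raise ConfigError(f"sampling: {exc}") from exc
        if sim.dt <= 0:
            raise ConfigError("simulation.dt: must be positive")
        if not (0 <= sim.seeding_fraction < 1):
            raise ConfigError("simulation.seeding_fraction: not in [0, 1)")
        if sim.record_interval < 1:
            raise ConfigError("simulation.record_interval: must be >= 1")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        sections = {"environment": EnvironmentConfig,
                    "sampling": SamplingConfig,
                    "simulation": SimulationSection,
                    "seeds": SeedsConfig}
        for name, klass in sections.items():
            sub = data.pop(name, {}) or {}
            allowed = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - allowed
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in '{name}': {sorted(unknown)}")
            kwargs[name] = klass(**sub)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if data:
            raise ConfigError(f"unknown top-level key(s): {sorted(data)}")
        return cls(schema_version=str(version), **kwargs).validate()


def load_config(path) -> RunConfig:
    """Load a YAML (.yaml/.yml) or TOML (.toml) run configuration; an empty
    file yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() == ".toml":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
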