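"""Run manifests: flat key-value configuration for simulations.

A manifest holds everything needed to reproduce a run: the rate parameters,
the grid settings, the abundance scale, the run length, the fishing scenario
and the resource mode.  It loads from a flat YAML (or JSON, a YAML subset)
mapping and serializes back to one, so every output can carry its full
parameter provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import CommunityState, ModelParams, SizeGrid, build_grid, initial_state
from .operators import FishingScenario, OperatorSet, build_operators

__all__ = ["ConfigError", "RunManifest", "load_manifest"]

PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
GRID_KEYS = {"m2", "delta", "k", "s"}
RUN_KEYS = {"a0", "years", "record_interval", "constant_resource",
            "pattern", "F0", "threshold_mass", "label"}
KNOWN_KEYS = PARAM_KEYS | GRID_KEYS | RUN_KEYS


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass(frozen=True)
class RunManifest:
    """A fully specified simulation: parameters, grid, scenario, horizon."""

    params: ModelParams = field(default_factory=ModelParams)
    m2: float = 0.001
    delta: float = 1.5
    k: int = 50
    s: int = 37
    a0: float = 0.01
    years: float = 40.0
    record_interval: float = 1.0
    constant_resource: bool = False
    pattern: str = "none"
    F0: float = 0.0
    threshold_mass: float | None = None
    label: str = "run"

    def __post_init__(self) -> None:
        if self.years <= 0:
            raise ConfigError(f"years must be positive, got {self.years}")

    @property
    def scenario(self) -> FishingScenario:
        return FishingScenario(self.pattern, self.F0, self.threshold_mass)

    def build(self) -> tuple[SizeGrid, OperatorSet, CommunityState]:
        """Assemble grid, operators and initial state for this manifest."""
        grid = build_grid(self.m2, self.delta, self.k, self.s)
        ops = build_operators(grid, self.params, self.scenario)
        return grid, ops, initial_state(grid, self.a0)

    def with_(self, **overrides) -> "RunManifest":
        """Copy with flat-key overrides (parameter, grid or run keys)."""
        return manifest_from_dict({**self.to_dict(), **overrides})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.update(m2=self.m2, delta=self.delta, k=self.k, s=self.s, a0=self.a0,
                 years=self.years, record_interval=self.record_interval,
                 constant_resource=self.constant_resource, pattern=self.pattern,
                 F0=self.F0, label=self.label)
        if self.threshold_mass is not None:
            d["threshold_mass"] = self.threshold_mass
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def manifest_from_dict(raw: dict) -> RunManifest:
    """Build a manifest from a flat mapping, rejecting unknown keys."""
    unknown = sorted(set(raw) - KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    try:
        params = ModelParams(**{k: v for k, v in raw.items() if k in PARAM_KEYS})
        extra = {k: v for k, v in raw.items() if k in (GRID_KEYS | RUN_KEYS)}
        return RunManifest(params=params, **extra)
    except (ValueError, TypeError) as err:
        if isinstance(err, ConfigError):
            raise
        raise ConfigError(str(err)) from err


def load_manifest(path: str | Path) -> RunManifest:
    """Load a manifest from a flat YAML/JSON config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a flat key-value mapping")
    return manifest_from_dict(raw)
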