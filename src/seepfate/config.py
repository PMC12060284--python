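"""Pipeline configuration: validation, defaults, serialization, hashing.

A single human-readable YAML mapping drives all stages; physical
defaults mirror the study inputs (65 m station, 4.5 mm pure-methane
bubble, a = 6.97e-7 s/m, Sc = 677, 1 m cells, 0.01 day steps, 1e-7
stop criterion, 36 ensemble members).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields

import yaml

from .kinetics import HALFLIFE_MIN


class ConfigError(ValueError):
    """Invalid pipeline configuration; .errors itemises the violations."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass
class PipelineConfig:
    station_depth: float = 65.0
    release_depth: float | None = None      # None: the station depth
    bubble_diameter: float = 4.5e-3         # m
    halflife_days: float = 50.0
    sweep_min: float | None = None          # set both to run a sweep
    sweep_max: float | None = None
    sweep_points: int = 25
    n_starts: int = 36
    run_ensemble: bool = False
    start_day: float = 0.0
    a_gas_transfer: float = 6.97e-7         # s/m
    schmidt: float = 677.0
    dz: float = 1.0                         # m
    dt: float = 0.01                        # days
    stop_fraction: float = 1e-7
    seed: int = 0
    outdir: str = "results"

    @property
    def effective_release_depth(self) -> float:
        return self.station_depth if self.release_depth is None else self.release_depth

    @property
    def sweep_requested(self) -> bool:
        return self.sweep_min is not None or self.sweep_max is not None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return validate_config(data)


def validate_config(data: dict) -> PipelineConfig:
    """Fill defaults, enforce physical ranges, reject unknown keys."""
    errors = []
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"unknown key: {key!r}")
    cfg = PipelineConfig(**{k: v for k, v in data.items() if k in known})

    if "station_depth" in data and (data["station_depth"] is None
                                    or not data["station_depth"] > 0):
        errors.append("station_depth must be positive")
    elif cfg.station_depth <= 0:
        errors.append("station_depth: missing or non-positive")
    if cfg.release_depth is not None and not 0 < cfg.release_depth <= cfg.station_depth:
        errors.append("release_depth must lie in (0, station_depth]")
    if not 1e-5 < cfg.bubble_diameter < 0.05:
        errors.append("bubble_diameter outside the modelled range (0.01-50 mm)")
    if not cfg.halflife_days >= HALFLIFE_MIN:
        errors.append(f"halflife_days must be >= {HALFLIFE_MIN} (physical support)")
    if cfg.sweep_requested:
        if cfg.sweep_min is None or cfg.sweep_max is None:
            errors.append("sweep needs both sweep_min and sweep_max")
        elif not 0 < cfg.sweep_min <= cfg.sweep_max:
            errors.append("sweep bounds must satisfy 0 < sweep_min <= sweep_max")
        if cfg.sweep_points < 2:
            errors.append("sweep_points must be >= 2")
    if cfg.n_starts < 1:
        errors.append("n_starts must be >= 1")
    if cfg.a_gas_transfer < 0 or cfg.schmidt <= 0:
        errors.append("surface-exchange constants must be positive")
    if cfg.dz <= 0 or cfg.dt <= 0:
        errors.append("dz and dt must be positive")
    if not 0 < cfg.stop_fraction < 1:
        errors.append("stop_fraction must lie in (0, 1)")

    if errors:
        raise ConfigError(errors)
    return cfg
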