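"""Simulation configuration: dataclasses, YAML loading and validation.

Defaults reproduce the reference numerical setup: sigma=8, b=1.9, c=1.5,
grid spacing dx=dy=0.125, time step dt=3.124e-4, a 50x50 domain, noise
of standard deviation 0.01 on zero initial fields, and periodic
boundaries.  A protocol is an ordered list of stages, each with a
duration and a forcing (A=0 for unforced stages); the forcing phase
restarts at each stage onset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .model import ForcingParams, ModelParams

__all__ = ["ProtocolStage", "SimulationConfig", "load_config", "save_config",
           "config_hash", "FAST_PRESET"]

#: scaled-down preset: quarter-resolution grid, larger step; the
#: reference study states grid spacing and time step within this range do
#: not change the patterns quantitatively
FAST_PRESET = {"nx": 100, "ny": 100, "dx": 0.25, "dt": 1e-3}

_CONFIG_KEYS = {
    "a", "b", "sigma", "c", "stages", "nx", "ny", "dx", "dy", "dt",
    "noise_sd", "seed", "snapshot_interval", "fast",
}
_STAGE_KEYS = {"duration", "A", "T"}


@dataclass(frozen=True)
class ProtocolStage:
    """One stage of a forcing protocol: hold the forcing (possibly A=0)
    for ``duration`` dimensionless time units."""

    duration: float
    forcing: ForcingParams = field(default_factory=ForcingParams)

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"stage duration must be > 0, got {self.duration}")

    def to_dict(self) -> dict:
        return {"duration": self.duration, **self.forcing.to_dict()}


@dataclass(frozen=True)
class SimulationConfig:
    params: ModelParams
    stages: tuple[ProtocolStage, ...]
    nx: int = 400
    ny: int = 400
    dx: float = 0.125
    dt: float = 3.124e-4
    noise_sd: float = 0.01
    seed: int = 0
    snapshot_interval: float = 10.0

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("at least one protocol stage is required")
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid must be at least 16x16")
        if not (self.dx > 0 and self.dt > 0):
            raise ValueError("dx and dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.snapshot_interval > 0):
            raise ValueError("snapshot_interval must be > 0")

    @property
    def domain_size(self) -> tuple[float, float]:
        return self.nx * self.dx, self.ny * self.dx

    @property
    def total_time(self) -> float:
        return sum(s.duration for s in self.stages)

    def to_dict(self) -> dict:
        return {
            **self.params.to_dict(),
            "stages": [s.to_dict() for s in self.stages],
            "nx": self.nx, "ny": self.ny, "dx": self.dx, "dt": self.dt,
            "noise_sd": self.noise_sd, "seed": self.seed,
            "snapshot_interval": self.snapshot_interval,
        }


def _build_config(data: dict) -> SimulationConfig:
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "a" not in data:
        raise ValueError("configuration must give the feed parameter 'a'")
    if "stages" not in data or not data["stages"]:
        raise ValueError("configuration must give a nonempty 'stages' list")
    if "dy" in data and float(data["dy"]) != float(data.get("dx", 0.125)):
        raise ValueError("dx and dy must be equal (uniform square grid)")
    params = ModelParams.from_dict(data)
    stages = []
    for i, s in enumerate(data["stages"]):
        bad = set(s) - _STAGE_KEYS
        if bad:
            raise ValueError(f"unknown keys in stage {i}: {sorted(bad)}")
        if "duration" not in s:
            raise ValueError(f"stage {i} is missing 'duration'")
        stages.append(
            ProtocolStage(duration=float(s["duration"]),
                          forcing=ForcingParams.from_dict(s))
        )
    numerics = {}
    if data.get("fast"):
        numerics.update(FAST_PRESET)
    for key in ("nx", "ny"):
        if key in data:
            numerics[key] = int(data[key])
    for key in ("dx", "dt", "noise_sd", "snapshot_interval"):
        if key in data:
            numerics[key] = float(data[key])
    if "seed" in data:
        numerics["seed"] = int(data["seed"])
    return SimulationConfig(params=params, stages=tuple(stages), **numerics)


def load_config(path) -> SimulationConfig:
    """Read and validate a YAML simulation configuration.

    Unknown keys are rejected by name; omitted numerics default to the
    reference setup.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return _build_config(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_hash(config: SimulationConfig) -> str:
    """Stable hex digest of the configuration (key order independent)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
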