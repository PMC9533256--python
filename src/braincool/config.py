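"""Structured run configuration (YAML) for the command-line entry points.

Every physical default of the model is overridable by key; a run's config
plus the code version reproduces its outputs bit-for-bit in deterministic
modes (the seed governs only synthetic-MRT noise).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .properties import BloodProperties, TissueProperties
from .solver import ProbeSpec, ShellSpec, SimulationDomain, SolverOptions


@dataclass(frozen=True)
class SweepConfig:
    temperatures: tuple = tuple(range(0, 41, 2))
    lengths: tuple = (12.5, 25.0, 50.0)
    cooling_time: float = 3600.0


@dataclass(frozen=True)
class MRTConfig:
    in_plane_extent: float = 64.0
    voxel_size: tuple = (2.0, 2.0, 5.0)
    n_slices: int = 3
    frame_interval: float = 7.8
    noise_sd: float = 0.5
    artifact_radius: float = 3.0


@dataclass
class RunConfig:
    """All parameters of a reproducible run."""

    tissue: TissueProperties = dc_field(default_factory=TissueProperties)
    blood: BloodProperties = dc_field(default_factory=BloodProperties)
    probe: ProbeSpec = dc_field(default_factory=ProbeSpec)
    domain: SimulationDomain = dc_field(default_factory=SimulationDomain)
    solver: SolverOptions = dc_field(default_factory=SolverOptions)
    sweep: SweepConfig = dc_field(default_factory=SweepConfig)
    mrt: MRTConfig = dc_field(default_factory=MRTConfig)
    times: tuple = (0.0, 136.0)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {"tissue": TissueProperties, "blood": BloodProperties,
             "probe": ProbeSpec, "domain": SimulationDomain,
             "solver": SolverOptions, "sweep": SweepConfig, "mrt": MRTConfig}


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in names:
            raise ConfigError(f"unknown key '{path}.{key}'")
        if cls is ProbeSpec and key == "shell" and isinstance(val, dict):
            val = _build(ShellSpec, val, f"{path}.shell")
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{path}': {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    cfg = RunConfig()
    for key, val in (data or {}).items():
        if key in _SECTIONS:
            setattr(cfg, key, _build(_SECTIONS[key], val or {}, key))
        elif key == "times":
            cfg.times = tuple(float(t) for t in val)
        elif key == "seed":
            cfg.seed = int(val)
        else:
            raise ConfigError(f"unknown top-level key '{key}'")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
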