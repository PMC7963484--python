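"""TOML run-configuration loading.

A run file may contain ``[events]``, ``[network]`` and ``[plasticity]``
tables whose keys mirror the corresponding dataclass fields; missing keys
fall back to the model defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

from .events import EventTrainConfig
from .network import NetworkParams
from .plasticity import PlasticityParams, SimConfig

__all__ = ["load_config", "config_to_dict"]


def _build(cls, section: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path) -> SimConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return SimConfig(
        events=_build(EventTrainConfig, raw.get("events", {})),
        network=_build(NetworkParams, raw.get("network", {})),
        plasticity=_build(PlasticityParams, raw.get("plasticity", {})),
        snapshot_times=tuple(raw.get("snapshot_times", ())),
        engine=raw.get("engine", "numba"),
    )


def config_to_dict(cfg: SimConfig) -> dict:
    return {
        "events": dataclasses.asdict(cfg.events),
        "network": dataclasses.asdict(cfg.network),
        "plasticity": dataclasses.asdict(cfg.plasticity),
        "snapshot_times": list(cfg.snapshot_times),
        "engine": cfg.engine,
    }
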