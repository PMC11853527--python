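"""Run configuration: one YAML/JSON document with per-module sections.

Unknown keys are rejected on load so typos fail loudly; temperature is set
exactly once and threaded to every module that needs RT.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .constants import DEFAULT_TEMPERATURE_K

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    temperature_K: float = DEFAULT_TEMPERATURE_K
    leak_k_sd: float = 3.0
    vthres_k_sd: float = 3.0
    delay_fraction: float = 0.1
    hotspot_window: int = 7
    salt_bridge_d_on: float = 4.0
    salt_bridge_s_hi: float = 0.65
    salt_bridge_s_lo: float = 0.25
    water_radius: float = 8.0
    water_bin_width: float = 0.5
    seed: int | None = None

    def validate(self) -> "RunConfig":
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")
        if self.hotspot_window % 2 == 0 or self.hotspot_window < 1:
            raise ValueError("hotspot_window must be odd and >= 1")
        if not 0 <= self.salt_bridge_s_lo <= self.salt_bridge_s_hi <= 1:
            raise ValueError("salt-bridge thresholds must satisfy 0<=lo<=hi<=1")
        return self

    def echo(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data).validate()
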