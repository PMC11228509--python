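"""YAML configuration for the sampler and noise schedule.

Schema (all keys optional, defaults from the dataclasses)::

    schedule:
      sigma_min: 0.01      # Angstrom
      sigma_max: 80.0
      rho: 7.0
      n_steps: 100
      sigma_data: 10.0
      p_mean: null         # default ln(sigma_data) - 1.2
      p_std: 1.2
    sampler:
      s_churn: 0.0
      step_scale: 1.0
      seed: 0
    stage2:
      start_sigma: 2.0
      n_steps: 25
      backbone_flex: 0.0

Unknown keys raise an error naming the key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from .diffusion import NoiseSchedule
from .sampling import SamplerConfig, Stage2Config


def _build(cls, section: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in section:
        if key not in valid:
            raise ValueError(f"unknown config key {where}.{key!r}")
    return cls(**section)


def load_config(path=None, overrides: dict | None = None) -> SamplerConfig:
    """Load a SamplerConfig from YAML, with optional override mapping."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    for key in raw:
        if key not in ("schedule", "sampler", "stage2"):
            raise ValueError(f"unknown config section {key!r}")
    if overrides:
        for dotted, value in overrides.items():
            section, _, name = dotted.partition(".")
            if not name:
                raise ValueError(f"override {dotted!r} must be section.key")
            raw.setdefault(section, {})[name] = value
    schedule = _build(NoiseSchedule, raw.get("schedule", {}), "schedule")
    sampler_kw = dict(raw.get("sampler", {}))
    for key in sampler_kw:
        if key not in ("s_churn", "step_scale", "seed"):
            raise ValueError(f"unknown config key sampler.{key!r}")
    stage2 = _build(Stage2Config, raw["stage2"], "stage2") if "stage2" in raw else None
    return SamplerConfig(schedule=schedule, stage2=stage2, **sampler_kw)


def config_digest(config: SamplerConfig) -> str:
    """Stable short hash of a config, for run manifests."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
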