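"""YAML configuration loading for architectures and stage parameters."""

from __future__ import annotations

from pathlib import Path

import yaml

from .abc_search import ABCConfig
from .network import NetworkArchitecture
from .synthetic import SyntheticSpec
from .trainer import TrainConfig

__all__ = ["load_config", "architecture_from_config", "abc_config_from_config",
           "train_config_from_config", "synthetic_spec_from_config"]


def load_config(path) -> dict:
    with open(Path(path)) as fh:
        return yaml.safe_load(fh) or {}


def architecture_from_config(cfg: dict) -> NetworkArchitecture:
    return NetworkArchitecture.from_dict(cfg.get("architecture", {}))


def abc_config_from_config(cfg: dict) -> ABCConfig:
    section = dict(cfg.get("abc", {}))
    for key in ("bounds", "phi_interval"):
        if key in section:
            section[key] = tuple(section[key])
    return ABCConfig(**section)


def train_config_from_config(cfg: dict) -> TrainConfig:
    return TrainConfig(**cfg.get("training", {}))


def synthetic_spec_from_config(cfg: dict) -> SyntheticSpec:
    return SyntheticSpec(**cfg.get("synthetic", cfg))
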