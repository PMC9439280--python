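"""Run configuration: defaults <- config file <- CLI flags.

Config files are YAML or JSON mappings with optional sections ``fmfe``
(``time`` / ``freq`` sub-sections), ``mfcc``, ``synthetic`` and
``evaluation``.  Every run serializes its fully resolved configuration next
to its outputs so results can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import yaml

from .core import FmfeConfig, MatchSettings
from .errors import ConfigError
from .mfcc import MfccConfig
from .synthetic import SyntheticConfig


def derive_seed(seed: int, module: str) -> int:
    """Fan one top-level seed out to a per-module seed (declared derivation)."""
    return (int(seed) + zlib.crc32(module.encode())) % (2**31)


def load_config_file(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must be a mapping")
    return data


def _update_dataclass(obj, values: dict, section: str):
    fields = {f.name for f in dataclasses.fields(obj)}
    for key, value in values.items():
        if key not in fields:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")
        setattr(obj, key, value)
    return obj


def build_fmfe_config(data: dict) -> FmfeConfig:
    cfg = FmfeConfig()
    section = data.get("fmfe", {})
    _update_dataclass(cfg.time, section.get("time", {}), "fmfe.time")
    _update_dataclass(cfg.freq, section.get("freq", {}), "fmfe.freq")
    cfg.validate()
    return cfg


def build_mfcc_config(data: dict) -> MfccConfig:
    cfg = _update_dataclass(MfccConfig(), data.get("mfcc", {}), "mfcc")
    cfg.validate()
    return cfg


def build_synthetic_config(data: dict) -> SyntheticConfig:
    cfg = _update_dataclass(SyntheticConfig(), data.get("synthetic", {}),
                            "synthetic")
    cfg.validate()
    return cfg


def resolved_snapshot(**sections) -> dict:
    """JSON-serializable view of every resolved config section."""
    out = {}
    for name, cfg in sections.items():
        if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
            out[name] = dataclasses.asdict(cfg)
        else:
            out[name] = cfg
    return out


def write_snapshot(snapshot: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(snapshot, indent=2, default=str) + "\n")
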