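"""YAML/JSON configuration covering every pipeline component.

A config file may contain any of the sections ``trial``, ``walk``,
``observer``, ``protocol``, ``tfce``, ``grid`` and ``rnn``; each maps 1:1
onto the corresponding dataclass.  CLI flags override config keys.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Type, TypeVar

import yaml

from .errors import ConfigError
from .mapping import GridSpec
from .observer import ObserverParams, ProtocolConfig
from .rnn.model import RnnConfig
from .tfce import TfceParams
from .trajectory import TrialConfig, WalkParams

SECTIONS: Dict[str, type] = {
    "trial": TrialConfig,
    "walk": WalkParams,
    "observer": ObserverParams,
    "protocol": ProtocolConfig,
    "tfce": TfceParams,
    "grid": GridSpec,
    "rnn": RnnConfig,
}

T = TypeVar("T")


def load_config(path: str | Path | None) -> Dict[str, dict]:
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown config sections {sorted(unknown)}")
    return raw


def build(section: str, config: Mapping[str, dict], **overrides) -> object:
    """Instantiate a section's dataclass from config + explicit overrides
    (overrides win; None overrides are ignored)."""
    cls = SECTIONS[section]
    kwargs = dict(config.get(section, {}))
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"section {section!r}: {exc}") from exc


def config_hash(config: Mapping) -> str:
    """Stable short hash of a config mapping, for run logging."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
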