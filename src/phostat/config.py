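"""YAML/JSON configuration loading for parameter sets."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .regulon import RegulonParams
from .transport import TransporterParams

__all__ = [
    "load_transporter_params",
    "load_regulon_params",
    "config_hash",
]


def _load_mapping(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def load_transporter_params(source) -> TransporterParams:
    """Build :class:`TransporterParams` from a mapping or YAML/JSON path."""
    data = _load_mapping(source)
    return TransporterParams(**{k: float(v) for k, v in data.items()})


def load_regulon_params(source) -> RegulonParams:
    """Build :class:`RegulonParams` from a mapping or YAML/JSON path.

    The schema mirrors the dataclass field names; ``params_L`` and
    ``params_H`` are nested transporter-parameter mappings.  ``K_S`` may
    be the string ``"inf"`` to disable Spl2 inhibition.  Omitted fields
    keep their defaults.
    """
    data = _load_mapping(source)
    kwargs: dict = {}
    for key, value in data.items():
        if key in ("params_L", "params_H"):
            kwargs[key] = load_transporter_params(value)
        elif key == "K_S":
            kwargs[key] = float(value)
        else:
            kwargs[key] = float(value)
    return RegulonParams(**kwargs)


def config_hash(data: dict) -> str:
    """Short stable hash of a configuration mapping (for output metadata)."""
    canon = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]
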