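"""Pipeline configuration: defaults and validated loading from YAML/JSON."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .dedup import DEFAULT_CUTOFF, DEFAULT_HASH_SIZE
from .info_filter import DEFAULT_THRESHOLD
from .ingest import ANISOTROPY_TOLERANCE, MAX_SOURCE_BYTES


@dataclass
class CurateConfig:
    """All tunables of the curation pipeline with their defaults."""

    patch_size: int = 224
    min_keep: int = 112
    anisotropy_tolerance: float = ANISOTROPY_TOLERANCE
    max_source_bytes: int = MAX_SOURCE_BYTES
    unify_polarity: bool = False
    clip_percentiles: Optional[Tuple[float, float]] = None
    hash_size: int = DEFAULT_HASH_SIZE
    cutoff: int = DEFAULT_CUTOFF
    threshold: float = DEFAULT_THRESHOLD
    top_k: int = 32
    selectivity_threshold: float = 0.3
    occlusion_window: int = 61
    occlusion_stride: int = 30
    seed: int = 42

    def to_dict(self) -> dict:
        return asdict(self)


_FIELD_TYPES = {
    "patch_size": int, "min_keep": int, "hash_size": int, "cutoff": int,
    "top_k": int, "occlusion_window": int, "occlusion_stride": int,
    "seed": int, "max_source_bytes": int,
    "anisotropy_tolerance": float, "threshold": float,
    "selectivity_threshold": float,
    "unify_polarity": bool,
}


def load_config(path=None, overrides: Optional[dict] = None) -> CurateConfig:
    """Load a YAML or JSON config file; absent keys take the defaults.

    Unknown keys are rejected; values of the wrong type raise naming the
    offending key. ``path=None`` (or an empty file) yields pure defaults.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    if overrides:
        data.update(overrides)

    known = set(CurateConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in _FIELD_TYPES.items():
        if key not in data:
            continue
        val = data[key]
        if typ is bool:
            if not isinstance(val, bool):
                raise TypeError(f"config key {key!r}: expected bool, "
                                f"got {type(val).__name__}")
        elif typ is int:
            if isinstance(val, bool) or not isinstance(val, int):
                raise TypeError(f"config key {key!r}: expected int, "
                                f"got {type(val).__name__}")
        elif typ is float:
            if isinstance(val, bool) or not isinstance(val, (int, float)):
                raise TypeError(f"config key {key!r}: expected number, "
                                f"got {type(val).__name__}")
            data[key] = float(val)
    if "clip_percentiles" in data and data["clip_percentiles"] is not None:
        cp = data["clip_percentiles"]
        if (not isinstance(cp, (list, tuple)) or len(cp) != 2
                or not all(isinstance(v, (int, float)) for v in cp)):
            raise TypeError("config key 'clip_percentiles': expected a "
                            "pair of numbers or null")
        data["clip_percentiles"] = (float(cp[0]), float(cp[1]))
    return CurateConfig(**data)
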