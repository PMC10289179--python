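"""YAML run configuration.

One document with optional blocks {phantom, enhance, train, refine, fuse,
loop}; unknown keys are rejected so typos fail loudly.  Every block maps
onto the corresponding parameter dataclass; missing keys take the
dataclass defaults.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .enhance import EnhancerParams
from .fuse import FusionParams
from .nnet import TrainConfig
from .phantom import PhantomConfig
from .pipeline import LoopConfig
from .refine import GrowParams

__all__ = ["load_config", "loop_config_from_dict"]

_BLOCKS = {
    "phantom": PhantomConfig,
    "enhance": EnhancerParams,
    "train": TrainConfig,
    "refine": GrowParams,
    "fuse": FusionParams,
}

_TUPLE_KEYS = {"shape", "radius_range", "soma_radius_range", "patch_shape", "split"}


def _build(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    d = {k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
         for k, v in d.items()}
    return cls(**d)


def loop_config_from_dict(doc: dict) -> LoopConfig:
    doc = dict(doc or {})
    sub = {}
    for block, cls in _BLOCKS.items():
        if block == "phantom":
            continue
        key = {"enhance": "enhancer", "train": "train", "refine": "grow",
               "fuse": "fusion"}[block]
        sub[key] = _build(cls, doc.pop(block, {}) or {})
    loop = doc.pop("loop", {}) or {}
    cfg = _build(LoopConfig, {**loop, **sub})
    if doc:
        raise ValueError(f"unknown top-level config blocks: {sorted(doc)}")
    return cfg


def load_config(path) -> LoopConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    doc.pop("phantom", None)  # phantom block is consumed by the phantom command
    return loop_config_from_dict(doc)


def load_phantom_config(path) -> PhantomConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return _build(PhantomConfig, doc.get("phantom", {}) or {})
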