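"""Packaged parameter presets and their loader."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .muscle import JointParams, MuscleParams
from .reflex import MuscleReflex, ReflexConfig

__all__ = ["Preset", "load_presets", "get_preset", "preset_names"]


@dataclass(frozen=True)
class Preset:
    """One named parameter set: muscle pair, joint, reflexes and run defaults."""

    name: str
    flexor: MuscleParams
    extensor: MuscleParams
    joint: JointParams
    reflex: ReflexConfig
    u_baseline: float
    defaults: dict = field(default_factory=dict)


def _build(name: str, doc: Mapping) -> Preset:
    muscle = dict(doc["muscle"])
    reflex = MuscleReflex(**doc["reflex"])
    return Preset(
        name=name,
        flexor=MuscleParams(**muscle, sign=+1),
        extensor=MuscleParams(**muscle, sign=-1),
        joint=JointParams(**doc["joint"]),
        reflex=ReflexConfig(flexor=reflex, extensor=reflex),
        u_baseline=float(doc.get("u_baseline", 0.0)),
        defaults=dict(doc.get("defaults", {})),
    )


def load_presets(path: str | Path | None = None) -> dict[str, Preset]:
    """Load all presets from a YAML file (packaged file by default)."""
    if path is None:
        text = (resources.files("dystonia_reflex") / "data" / "presets.yaml"
                ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    return {name: _build(name, doc) for name, doc in raw.items()}


def preset_names() -> tuple[str, ...]:
    return tuple(load_presets())


def get_preset(name: str, path: str | Path | None = None) -> Preset:
    presets = load_presets(path)
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}") from None
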