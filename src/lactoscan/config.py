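"""Run configuration: YAML parsing, validation, and run manifests.

A config file has up to four sections — ``segmentation``, ``linking``,
``scene``, and top-level run keys (``tile_size``, ``overlap``,
``attribution_mode``, ``pixel_size``, ``seed``, ``log_level``).  Unknown
keys anywhere are rejected so that typos never silently fall back to
defaults; *missing* keys do fall back to the documented defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .link import LinkParams
from .segment import SegmentationParams
from .synthetic import SceneParams

__all__ = ["RunConfig", "load_config"]

_TOP_KEYS = {
    "tile_size",
    "overlap",
    "attribution_mode",
    "pixel_size",
    "seed",
    "log_level",
    "channel_map",
}


@dataclass
class RunConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    linking: LinkParams = field(default_factory=LinkParams)
    scene: SceneParams = field(default_factory=SceneParams)
    tile_size: int | None = None
    overlap: int = 64
    attribution_mode: str = "intensity"
    pixel_size: float = 1.0
    seed: int = 0
    log_level: str = "INFO"
    channel_map: dict = field(default_factory=lambda: {"dic": 0, "rna": 1, "dna": 2})

    def manifest(self, extra: dict | None = None) -> dict:
        """Serializable record of the effective configuration."""
        from . import __version__

        out = {
            "package": "lactoscan",
            "version": __version__,
            "segmentation": dataclasses.asdict(self.segmentation),
            "linking": dataclasses.asdict(self.linking),
            "scene": dataclasses.asdict(self.scene),
            "tile_size": self.tile_size,
            "overlap": self.overlap,
            "attribution_mode": self.attribution_mode,
            "pixel_size": self.pixel_size,
            "seed": self.seed,
            "channel_map": self.channel_map,
        }
        if extra:
            out.update(extra)
        return out

    def write_manifest(self, path, extra: dict | None = None) -> None:
        Path(path).write_text(json.dumps(self.manifest(extra), indent=2, default=str))


def _build(cls, section: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown {name} config key(s): {sorted(unknown)}")
    kwargs = dict(section)
    # YAML has no tuple type; coerce list-valued fields the dataclasses expect
    for key in ("globule_radius_lognormal", "crescent_arc"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    ``overrides`` (CLI flags) take precedence over file values; values of
    None in overrides are ignored.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        raw = loaded
    unknown = set(raw) - _TOP_KEYS - {"segmentation", "linking", "scene"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(
        segmentation=_build(SegmentationParams, raw.get("segmentation", {}), "segmentation"),
        linking=_build(LinkParams, raw.get("linking", {}), "linking"),
        scene=_build(SceneParams, raw.get("scene", {}), "scene"),
        **{k: raw[k] for k in _TOP_KEYS & set(raw)},
    )
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if not hasattr(cfg, key):
            raise ValueError(f"unknown override {key!r}")
        setattr(cfg, key, value)
    return cfg
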