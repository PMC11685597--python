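"""Declarative pipeline configuration with strict YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .containers import ValidationError
from .simulate import SimConfig


@dataclass
class QcParams:
    min_counts: int = 500
    min_features: int = 330
    max_features: int = 8950
    low_quality_rule: str = "either"


@dataclass
class MiogParams:
    mode: str = "miog"  # or "intersection"
    n_hvgs: int = 1000


@dataclass
class XmapParams:
    train_fraction: float = 0.67
    cap: int = 300
    threshold: float = 0.5
    n_estimators: int = 80
    max_depth: int = 4
    learning_rate: float = 0.3


@dataclass
class RosaParams:
    q: int = 100
    max_size: int = 50
    min_size: int = 20
    zmode: str = "scaled_log_cpm"
    top_sd: int = 700


@dataclass
class GseaParams:
    k: int = 50
    n_perm: int = 10_000
    weight_exponent: float = 1.0
    perm_unit: str = "cells"


@dataclass
class TreeParams:
    n_bootstrap: int = 100


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, round-trippable through YAML.

    One global ``seed`` fans out deterministically to per-stage seeds (CRC32
    of the stage name mixed with the seed), so any stage can be rerun in
    isolation and reproduce its in-pipeline output.
    """

    seed: int = 0
    outdir: str = "crosstype_run"
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcParams = field(default_factory=QcParams)
    trees: TreeParams = field(default_factory=TreeParams)
    miog: MiogParams = field(default_factory=MiogParams)
    xmap: XmapParams = field(default_factory=XmapParams)
    rosa: RosaParams = field(default_factory=RosaParams)
    gsea: GseaParams = field(default_factory=GseaParams)

    def stage_seed(self, stage: str) -> int:
        return (zlib.crc32(stage.encode()) ^ (self.seed * 2654435761)) % (2**31)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build(cls, raw, path="")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        payload = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SECTIONS = {
    "sim": SimConfig,
    "qc": QcParams,
    "trees": TreeParams,
    "miog": MiogParams,
    "xmap": XmapParams,
    "rosa": RosaParams,
    "gsea": GseaParams,
}


def _build(cls, raw: dict, path: str):
    """Construct nested config dataclasses, rejecting unknown keys."""
    if not isinstance(raw, dict):
        raise ValidationError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValidationError(
            f"unknown config key(s) {sorted(unknown)} in section {path or '<root>'}"
        )
    kwargs = {}
    for name in fields:
        if name not in raw:
            continue
        value = raw[name]
        if cls is PipelineConfig and name in _SECTIONS:
            kwargs[name] = _build(
                _SECTIONS[name], value, path=f"{path}.{name}" if path else name
            )
        elif name == "homology_map" and isinstance(value, dict):
            kwargs[name] = {int(k): int(v) for k, v in value.items()}
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _plain(obj):
    """Make a config dict YAML/JSON-safe (int keys -> str on dump is avoided
    by keeping homology_map keys as ints, which YAML handles natively)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
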