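"""Run configuration: YAML schema shared by the CLI and the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .beta import NullModelConfig
from .simulate import AssemblyConfig


@dataclasses.dataclass
class SyntheticConfig:
    """Synthetic-landscape block: assembly knobs plus attribute ranges and traits."""

    assembly: AssemblyConfig = dataclasses.field(default_factory=AssemblyConfig)
    area_range_ha: tuple[float, float] = (0.25, 50.0)
    dni_range_m: tuple[float, float] = (5.0, 80.0)
    dm_range_m: tuple[float, float] = (500.0, 4000.0)
    trait_separation: float = 6.0
    trait_clusters: int = 4


@dataclasses.dataclass
class InputPaths:
    community: str
    attributes: str
    traits: str | None = None


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    inputs: InputPaths | None = None
    null_model: NullModelConfig = dataclasses.field(default_factory=NullModelConfig)
    area_cut_ha: float = 1.0
    dni_cut_m: float = 50.0
    dm_cut_m: float = 2000.0
    pft_k: int = 4
    pft_n_init: int = 10
    hierarchy: bool = True
    reduction: str = "difference"

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' and 'inputs' must be configured")

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def _pick(d: dict, cls):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**d)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    synth = raw.pop("synthetic", None)
    inputs = raw.pop("inputs", None)
    null = raw.pop("null_model", None)
    kwargs = dict(raw)
    if synth is not None:
        synth = dict(synth)
        assembly_keys = {f.name for f in dataclasses.fields(AssemblyConfig)}
        assembly = {k: synth.pop(k) for k in list(synth) if k in assembly_keys}
        for key in ("area_range_ha", "dni_range_m", "dm_range_m"):
            if key in synth:
                synth[key] = tuple(synth[key])
        kwargs["synthetic"] = SyntheticConfig(assembly=AssemblyConfig(**assembly), **synth)
    if inputs is not None:
        kwargs["inputs"] = _pick(dict(inputs), InputPaths)
    if null is not None:
        kwargs["null_model"] = _pick(dict(null), NullModelConfig)
    return _pick(kwargs, RunConfig)


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return config_from_dict(raw)
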