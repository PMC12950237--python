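"""Nested run configuration with strict, lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .model import ModelConfig, TransformerConfig
from .preprocess import PreprocessConfig
from .train import TrainConfig


@dataclass
class SynthConfig:
    classes: tuple = ("CHEW", "MUSC", "ELEC", "EYEM", "RC", "BLINK")
    per_class: int = 400
    duration_s: float = 4.0
    fs: float = 250.0
    snr_db: float = 10.0
    alpha_power: float = 0.3
    seed: int = 0


@dataclass
class TfrConfig:
    window_len: int = 250
    overlap: int = 200
    log_scale: bool = True


def _strict_build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section '{path}'")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        nested = {"transformer": TransformerConfig}.get(key)
        if nested and isinstance(value, dict):
            kwargs[key] = _strict_build(nested, value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Every stage's parameters in one serializable object."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tfr: TfrConfig = field(default_factory=TfrConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    _SECTIONS = {
        "synth": SynthConfig, "preprocess": PreprocessConfig, "tfr": TfrConfig,
        "model": ModelConfig, "training": TrainConfig,
    }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - (set(cls._SECTIONS) | {"seed"})
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _strict_build(section_cls, data[name], name)
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        text = yaml.safe_dump(clean(self.to_dict()), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        if "\n" in str(path_or_text):
            data = yaml.safe_load(str(path_or_text))
        else:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
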