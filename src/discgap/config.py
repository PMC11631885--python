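"""Run configuration: one JSON document driving every CLI subcommand.

Unknown keys are rejected so typos fail loudly instead of silently
falling back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .model import LossConfig, ModelConfig, TrainConfig
from .phantom import PhantomParams


@dataclass(frozen=True)
class QuantifyParams:
    min_area_px: int = 50
    min_run_px: int = 5


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    phantom: PhantomParams = field(default_factory=PhantomParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "quantify": QuantifyParams,
            "model": ModelConfig,
            "train": TrainConfig,
            "loss": LossConfig,
            "phantom": PhantomParams,
        }
        kwargs: dict = {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        for key, value in data.items():
            if key in sections:
                sub_cls = sections[key]
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown keys in '{key}': {sorted(sub_unknown)}"
                    )
                value = dict(value)
                for k, v in value.items():
                    if isinstance(v, list):
                        value[k] = tuple(v)
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
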