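"""Pipeline configuration: one object holding every tunable parameter,
round-trippable through YAML.

The conditioning defaults (resample ×2, grow 5, smooth 3, shrink 5) and
line-smoothing defaults (0.85, 0.05, 200) live on
:class:`otomorph.maskops.ConditioningParams` and
:class:`otomorph.centerline.SmoothingParams` respectively — each number
is defined in exactly one place.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .centerline import SmoothingParams
from .maskops import ConditioningParams
from .register import RegistrationOptions

__all__ = ["PipelineConfig", "load_config", "save_config"]

DEFAULT_LABEL_MAP = {
    "scala_media": 1,
    "crista_anterior": 2,
    "crista_lateral": 3,
    "crista_posterior": 4,
    "macula_utriculi": 5,
    "macula_sacculi": 6,
}


@dataclass
class PipelineConfig:
    conditioning: ConditioningParams = field(default_factory=ConditioningParams)
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    output_dir: str = "otomorph_out"
    seed: int = 0

    def label_of(self, name: str) -> int:
        if name not in self.label_map:
            raise ValueError(f"no label configured for {name!r}; label_map: {self.label_map}")
        return int(self.label_map[name])

    @property
    def organ_labels(self) -> list[int]:
        return [
            int(v) for k, v in self.label_map.items() if k != "scala_media"
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["registration"]["stage_steps"] = [
            list(s) for s in d["registration"]["stage_steps"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cond = ConditioningParams(**d.get("conditioning", {}))
        smooth = SmoothingParams(**d.get("smoothing", {}))
        reg_d = dict(d.get("registration", {}))
        if "stage_steps" in reg_d:
            reg_d["stage_steps"] = tuple(tuple(s) for s in reg_d["stage_steps"])
        reg = RegistrationOptions(**reg_d)
        return cls(
            conditioning=cond,
            smoothing=smooth,
            registration=reg,
            label_map=dict(d.get("label_map", DEFAULT_LABEL_MAP)),
            output_dir=d.get("output_dir", "otomorph_out"),
            seed=int(d.get("seed", 0)),
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return path
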