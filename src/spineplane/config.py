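"""Run configuration: every tunable constant with its default, YAML-loadable."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .yolo3d import AnchorSpec, LossWeights, YoloConfig

__all__ = ["YoloRunConfig", "SegRunConfig", "PhantomRunConfig", "RunConfig", "load_config"]


@dataclass
class YoloRunConfig:
    input_size: int = 160
    width_multiplier: float = 1.0
    anchor_scale1: float = 0.15
    anchor_scale2: float = 0.11
    anchor_scale3: float = 0.07
    conf_threshold: float = 0.10
    iou_threshold: float = 0.15
    classprob_threshold: float = 0.25
    w_OL: float = 1.0
    w_NOL: float = 10.0
    w_BL: float = 10.0
    w_CL: float = 1.0
    w_APL: float = 1.0
    w_CPL: float = 1.0
    w_SPL: float = 1.0
    lr: float = 1e-5
    weight_decay: float = 1e-4
    epochs: int = 1000

    def net_config(self) -> YoloConfig:
        return YoloConfig(
            input_size=self.input_size,
            width_multiplier=self.width_multiplier,
            anchor=AnchorSpec(self.anchor_scale1, self.anchor_scale2, self.anchor_scale3),
        )

    def loss_weights(self) -> LossWeights:
        return LossWeights(
            self.w_OL, self.w_NOL, self.w_BL, self.w_CL, self.w_APL, self.w_CPL, self.w_SPL
        )


@dataclass
class SegRunConfig:
    depth: int = 3
    base_width: int = 16
    patch_size: int = 64
    dbscan_eps: float = 2.0
    dbscan_min_samples: int = 10
    w_CE: float = 1.0
    w_DC: float = 1.0
    lr: float = 1e-2
    momentum: float = 0.99
    weight_decay: float = 3e-5
    epochs: int = 1000


@dataclass
class PhantomRunConfig:
    grid_size: int = 160
    region: str = "mixed"
    max_tilt_deg: float = 15.0
    noise: float = 0.02
    artifact_severity: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    yolo: YoloRunConfig = field(default_factory=YoloRunConfig)
    seg: SegRunConfig = field(default_factory=SegRunConfig)
    phantom: PhantomRunConfig = field(default_factory=PhantomRunConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        f = names[k]
        if dataclasses.is_dataclass(f.type) or f.name in ("yolo", "seg", "phantom", "augment"):
            sub = {"yolo": YoloRunConfig, "seg": SegRunConfig,
                   "phantom": PhantomRunConfig, "augment": AugmentConfig}[f.name]
            kwargs[k] = _build(sub, v or {}, f"{path}.{k}")
        else:
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
    return cls(**kwargs)


def load_config(path=None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(RunConfig, data, "config")
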