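"""Run configuration: YAML-backed, schema-validated, full-scale defaults.

The default (``full``) profile is the production training recipe
(300 epochs, batch 24, 256-px tiles, Adam 1e-3 -> 1e-4 at epoch 150); the
``tiny`` profile is the CPU-scale variant used by the test suite.
Unknown keys are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "tiny_profile"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IoSection(_Section):
    normalize_low_pct: float = 1.0
    normalize_high_pct: float = 99.9


class AugmentationSection(_Section):
    rotation_deg: tuple[float, float] = (0.0, 360.0)
    translation_frac: tuple[float, float] = (-0.1, 0.1)
    zoom: tuple[float, float] = (0.8, 1.2)
    flip_h: float = 0.5
    flip_v: float = 0.5
    intensity_jitter: tuple[float, float] = (-0.1, 0.1)


class ModelSection(_Section):
    architecture: Literal["linknet"] = "linknet"
    encoder: Literal["vgg16_style", "tiny"] = "vgg16_style"
    input_tile: int = 256
    out_channels: int = 7
    width_multiplier: float = 1.0


class TrainSection(_Section):
    epochs: int = 300
    batch_size: int = 24
    lr_phase1: float = 1e-3
    lr_phase2: float = 1e-4
    phase_split_epoch: int = 150
    optimizer: Literal["adam"] = "adam"
    loss_eps: float = 1.0
    loss_per_channel: bool = True
    augment: bool = True


class FusionSection(_Section):
    threshold: float = 0.5
    seed_binarize_level: float = 0.5
    boundary_channel_weights: tuple[float, ...] = (1.0,) * 7
    h_min: float = 0.02
    min_region_px: int = 4


class SynthSection(_Section):
    shape: tuple[int, int] = (128, 128)
    density: float = 30.0
    giant_fraction: float = 0.0
    size_ratio: float = 12.0
    boundary_intensity: float = 0.85
    cytoplasm_intensity: float = 0.25
    staining_mode: Literal["continuous", "dotted"] = "continuous"
    psf_sigma: float = 1.0
    gaussian_noise_sd: float = 0.04
    gradient_amplitude: float = 0.1


class RunConfig(_Section):
    io: IoSection = Field(default_factory=IoSection)
    augmentation: AugmentationSection = Field(default_factory=AugmentationSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    fusion: FusionSection = Field(default_factory=FusionSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def load_config(path: str | None = None, profile: str | None = None) -> RunConfig:
    """Load a YAML config; ``profile='tiny'`` applies the CPU-scale preset."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = RunConfig(**data)
    if profile == "tiny":
        cfg = tiny_profile(cfg)
    elif profile not in (None, "full"):
        raise ValueError(f"unknown profile {profile!r}")
    return cfg


def tiny_profile(base: RunConfig | None = None) -> RunConfig:
    """CPU-scale profile: 64-px tiles, 1/8-width network, short schedule."""
    cfg = base or RunConfig()
    return cfg.model_copy(
        update={
            "model": cfg.model.model_copy(
                update={"encoder": "tiny", "input_tile": 64, "width_multiplier": 0.125}
            ),
            "train": cfg.train.model_copy(
                update={"epochs": 60, "batch_size": 4, "phase_split_epoch": 30}
            ),
        }
    )
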