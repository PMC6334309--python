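"""YAML run configuration: schema, validation, presets.

A run config selects a scale preset (``tiny`` for CPU-scale runs, ``paper``
for the full-scale hyperparameters: WGAN 1000 epochs at lr 5e-5, fine-tuning
30 epochs at lr 1e-4, dropout 0.5) and optionally overrides individual stage
fields. Unknown keys are rejected so typos cannot silently fall back to
defaults, and every loaded config is echoed in full into the run manifest.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .augment import AugmentConfig
from .classifier import ClassifierArch, FinetuneConfig, PretrainConfig
from .evaluation import CVParams, Strategy
from .phantom import PhantomConfig
from .wgan import WGANConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")

    def overrides(self) -> dict:
        return {k: v for k, v in self.model_dump().items() if v is not None}


class PhantomSection(_Section):
    n_benign: Optional[int] = Field(None, ge=0)
    n_malignant: Optional[int] = Field(None, ge=0)
    volume_shape: Optional[tuple[int, int, int]] = None
    voxel_spacing: Optional[tuple[float, float, float]] = None
    lung_background_intensity: Optional[float] = None
    nodule_intensity: Optional[float] = None
    noise_sigma: Optional[float] = Field(None, ge=0)
    diameter_range_mm: Optional[tuple[float, float]] = None
    spicule_count_range: Optional[tuple[int, int]] = None
    spicule_length_fraction: Optional[float] = Field(None, gt=0)
    pleural_attachment_prob: Optional[float] = Field(None, ge=0, le=1)
    chest_wall: Optional[bool] = None


class VOISection(_Section):
    resolution_mm: Optional[float] = Field(None, gt=0)


class AugmentSection(_Section):
    angle_min: Optional[float] = None
    angle_max: Optional[float] = None
    angle_step: Optional[float] = Field(None, gt=0)
    tilt_axes: Optional[tuple[str, ...]] = None
    include_axial: Optional[bool] = None
    symmetry_ops: Optional[tuple[str, ...]] = None


class WGANSection(_Section):
    latent_dim: Optional[int] = Field(None, ge=1)
    lr: Optional[float] = Field(None, gt=0)
    epochs: Optional[int] = Field(None, ge=0)
    clip_value: Optional[float] = Field(None, gt=0)
    n_critic: Optional[int] = Field(None, ge=1)
    batch_size: Optional[int] = Field(None, ge=1)
    image_size: Optional[int] = Field(None, ge=8)
    base_channels: Optional[int] = Field(None, ge=1)


class TrainSection(_Section):
    epochs: Optional[int] = Field(None, ge=0)
    lr: Optional[float] = Field(None, gt=0)
    momentum: Optional[float] = Field(None, ge=0, lt=1)
    batch_size: Optional[int] = Field(None, ge=1)


class EvaluationSection(_Section):
    k: Optional[int] = Field(None, ge=1)
    aggregate: Optional[Literal["mean", "median", "axial"]] = None
    n_generated_per_class: Optional[int] = Field(None, ge=1)
    strategies: Optional[list[Literal["scratch", "wgan-pretrained"]]] = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    master_seed: int = 0
    preset: Literal["tiny", "paper"] = "tiny"
    out_root: str = "runs"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    voi: VOISection = Field(default_factory=VOISection)
    augment: AugmentSection = Field(default_factory=AugmentSection)
    wgan: WGANSection = Field(default_factory=WGANSection)
    pretrain: TrainSection = Field(default_factory=TrainSection)
    finetune: TrainSection = Field(default_factory=TrainSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    # ------------------------------------------------------------------
    def cohort_sizes(self) -> tuple[int, int]:
        ov = self.phantom.overrides()
        if self.preset == "tiny":
            return ov.get("n_benign", 10), ov.get("n_malignant", 10)
        return ov.get("n_benign", 27), ov.get("n_malignant", 33)

    def phantom_config(self) -> PhantomConfig:
        ov = self.phantom.overrides()
        ov.pop("n_benign", None)
        ov.pop("n_malignant", None)
        return PhantomConfig(**ov)

    def cv_params(self) -> CVParams:
        base = CVParams.tiny(seed=self.master_seed) if self.preset == "tiny" else CVParams(seed=self.master_seed)
        base = replace(
            base,
            augment=replace(base.augment, **self.augment.overrides()),
            wgan=replace(base.wgan, **self.wgan.overrides()),
            pretrain=replace(base.pretrain, **self.pretrain.overrides()),
            finetune=replace(base.finetune, **self.finetune.overrides()),
        )
        ev = self.evaluation.overrides()
        for key in ("k", "aggregate", "n_generated_per_class"):
            if key in ev:
                base = replace(base, **{key: ev[key]})
        voi_ov = self.voi.overrides()
        if "resolution_mm" in voi_ov:
            base = replace(base, voi_resolution_mm=voi_ov["resolution_mm"])
        return base

    def strategies(self) -> list[Strategy]:
        names = self.evaluation.strategies or ["scratch", "wgan-pretrained"]
        return [Strategy("wgan" if n == "wgan-pretrained" else "none", augmented=True) for n in names]

    def echo(self) -> dict:
        """Full effective configuration (defaults filled) for the run log."""
        params = self.cv_params()
        n_b, n_m = self.cohort_sizes()
        return {
            "master_seed": self.master_seed,
            "preset": self.preset,
            "cohort": {"n_benign": n_b, "n_malignant": n_m},
            "phantom": asdict(self.phantom_config()),
            "voi_resolution_mm": params.voi_resolution_mm,
            "augment": asdict(params.augment),
            "wgan": asdict(params.wgan),
            "pretrain": asdict(params.pretrain),
            "finetune": asdict(params.finetune),
            "classifier_arch": asdict(params.arch),
            "evaluation": {
                "k": params.k,
                "aggregate": params.aggregate,
                "n_generated_per_class": params.n_generated_per_class,
                "strategies": [s.name for s in self.strategies()],
            },
        }


def load_config(path) -> RunConfig:
    """Load + validate a YAML run config; an empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(exclude_defaults=True) or {}))
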