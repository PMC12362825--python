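"""Schema-validated run configuration and deterministic seed fan-out.

A single YAML file drives the whole pipeline; unknown keys are rejected
and a resolved copy is written into every output directory.  Defaults
are the desk-scale preset (642-vertex template, latent 32), sized so the
full chain runs in minutes on one CPU; the full-scale reference
architecture values live in the spec dataclasses of the individual
modules and can be selected from the same schema.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .diffusion import PriorNetSpec, PriorTrainConfig, make_schedule
from .networks import FaceAutoencoderSpec, SnpEncoderSpec
from .simulate import SimConfig
from .training import AlignTrainConfig

__all__ = ["RunConfig", "load_config", "stage_seed", "STAGE_OFFSETS"]

# documented counter scheme: stage seed = (global seed * 10007 + offset) mod 2^31
STAGE_OFFSETS = {
    "simulate": 1, "align": 2, "prior": 3, "generate": 4,
    "evaluate": 5, "dropout": 6, "attribute": 7,
}


def stage_seed(global_seed: int, stage: str) -> int:
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    return (int(global_seed) * 10007 + STAGE_OFFSETS[stage]) % (2**31)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_samples: int = 600
    n_snps: int = 400
    template_level: int = 3
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal_per_feature: int = 25
    n_global_fields: int = 3
    n_causal_per_global: int = 15
    feature_effect_mm: float = 3.0
    global_effect_mm: float = 1.5
    age_effect_mm: float = 0.5
    sex_effect_mm: float = 1.0
    bmi_effect_mm: float = 0.5
    noise_mm: float = 0.2
    train_fraction: float = 0.8

    def build(self, seed: int) -> SimConfig:
        return SimConfig(
            n_samples=self.n_samples, n_snps=self.n_snps,
            template_level=self.template_level,
            maf_range=(self.maf_low, self.maf_high),
            n_causal_per_feature=self.n_causal_per_feature,
            n_global_fields=self.n_global_fields,
            n_causal_per_global=self.n_causal_per_global,
            feature_effect_mm=self.feature_effect_mm,
            global_effect_mm=self.global_effect_mm,
            age_effect_mm=self.age_effect_mm,
            sex_effect_mm=self.sex_effect_mm,
            bmi_effect_mm=self.bmi_effect_mm,
            noise_mm=self.noise_mm, train_fraction=self.train_fraction,
            seed=seed)


class FaceModelSection(_Strict):
    conv_channels: list[int] = [16, 16, 32]
    pool_factors: list[int] = [4, 4, 4]
    spiral_lengths: list[int] = [9, 9, 9]
    spiral_dilations: list[int] = [1, 1, 1]
    latent: int = 32

    def build(self) -> FaceAutoencoderSpec:
        return FaceAutoencoderSpec(
            conv_channels=list(self.conv_channels),
            pool_factors=list(self.pool_factors),
            spiral_lengths=list(self.spiral_lengths),
            spiral_dilations=list(self.spiral_dilations),
            latent=self.latent)


class SnpModelSection(_Strict):
    model_dim: int = 64
    ff_dim: int = 128
    layers: int = 2
    heads: int = 4
    dropout: float = 0.1
    layernorm_eps: float = 1e-5
    chunk_size: int = 100
    latent: int = 32
    input_dropout: float = 0.2

    def build(self) -> SnpEncoderSpec:
        return SnpEncoderSpec(
            model_dim=self.model_dim, ff_dim=self.ff_dim, layers=self.layers,
            heads=self.heads, dropout=self.dropout,
            layernorm_eps=self.layernorm_eps, chunk_size=self.chunk_size,
            latent=self.latent, input_dropout=self.input_dropout)


class PriorModelSection(_Strict):
    embed_dim: int = 64
    depth: int = 2
    heads: int = 4
    head_dim: int = 16
    ff_mult: int = 2
    dropout: float = 0.1
    covariates: list[str] = []

    def build(self, latent: int) -> PriorNetSpec:
        return PriorNetSpec(
            embed_dim=self.embed_dim, depth=self.depth, heads=self.heads,
            head_dim=self.head_dim, ff_mult=self.ff_mult,
            dropout=self.dropout, latent=latent,
            covariates=list(self.covariates))


class ScheduleSection(_Strict):
    timesteps: int = 250
    kind: str = "linear"
    beta_start: float = 1e-4
    beta_end: float = 0.06

    def build(self):
        return make_schedule(self.timesteps, self.kind,
                             self.beta_start, self.beta_end)


class AlignSection(_Strict):
    alpha: float = 10.0
    beta1: float = 1.0
    beta2: float = 1.0
    batch_size: int = 32
    lr_core: float = 1e-3
    wd_core: float = 0.01
    lr_decoder: float = 2e-3
    wd_decoder: float = 1e-5
    lr_decay: float = 0.99
    epochs: int = 60

    def build(self, seed: int) -> AlignTrainConfig:
        return AlignTrainConfig(
            alpha=self.alpha, beta1=self.beta1, beta2=self.beta2,
            batch_size=self.batch_size, lr_core=self.lr_core,
            wd_core=self.wd_core, lr_decoder=self.lr_decoder,
            wd_decoder=self.wd_decoder, lr_decay=self.lr_decay,
            epochs=self.epochs, seed=seed)


class PriorTrainSection(_Strict):
    lr: float = 1e-3
    weight_decay: float = 1e-3
    max_grad_norm: float = 0.5
    ema_beta: float = 0.98
    ema_update_every: int = 10
    steps: int = 3000
    batch_size: int = 64

    def build(self, seed: int) -> PriorTrainConfig:
        return PriorTrainConfig(
            lr=self.lr, weight_decay=self.weight_decay,
            max_grad_norm=self.max_grad_norm, ema_beta=self.ema_beta,
            ema_update_every=self.ema_update_every, steps=self.steps,
            batch_size=self.batch_size, seed=seed)


class EvalSection(_Strict):
    rank_percents: list[float] = [1.0, 10.0, 20.0]
    n_dpp_items: int = 40


class DropoutSection(_Strict):
    fractions: list[float] = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
    mask_seeds: list[int] = [0, 1]


class AttributeSection(_Strict):
    n_baselines: int = 50
    n_points: int = 20
    top_k: list[int] = [200, 500]
    features: list[str] = ["nose_protrusion", "eye_depth", "cheek_width"]


class RunConfig(_Strict):
    seed: int = 0
    sim: SimSection = SimSection()
    face_model: FaceModelSection = FaceModelSection()
    snp_model: SnpModelSection = SnpModelSection()
    prior_model: PriorModelSection = PriorModelSection()
    schedule: ScheduleSection = ScheduleSection()
    align: AlignSection = AlignSection()
    prior_train: PriorTrainSection = PriorTrainSection()
    evaluation: EvalSection = EvalSection()
    dropout: DropoutSection = DropoutSection()
    attribute: AttributeSection = AttributeSection()

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def dump(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` replace top-level keys."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    return RunConfig(**raw)
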