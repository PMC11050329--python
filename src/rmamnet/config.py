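"""Schema-validated pipeline configuration (YAML).

Every CLI stage reads a single YAML file with nested sections; unknown
keys are rejected before any stage runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .features import FeatureConfig
from .network import NetworkSpec, RMAMSpec
from .synth import CorpusConfig, SpeciesProfile, default_profiles

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesSection(_Strict):
    name: str
    band_center_hz: float
    band_width_hz: float
    pulse_rate_hz: float
    attack_ms: float = 1.5
    decay_ms: float = 15.0
    amplitude_cv: float = 0.3
    waveform_shape: str = "sine_burst"

    def build(self) -> SpeciesProfile:
        return SpeciesProfile(**self.model_dump())


class CorpusSection(_Strict):
    seed: int = 0
    sample_rate_hz: int = 44_100
    minutes_per_class: float = 1.0
    noise_to_signal_ratio: float = 1.2
    snr_db: float = 10.0
    n_days: int = 1
    species_profiles: list[SpeciesSection] | None = None

    def build(self) -> CorpusConfig:
        profiles = (
            tuple(p.build() for p in self.species_profiles)
            if self.species_profiles
            else default_profiles()
        )
        return CorpusConfig(
            seed=self.seed,
            sample_rate_hz=self.sample_rate_hz,
            minutes_per_class=self.minutes_per_class,
            noise_to_signal_ratio=self.noise_to_signal_ratio,
            snr_db=self.snr_db,
            n_days=self.n_days,
            species_profiles=profiles,
        )


class FeatureSection(_Strict):
    target_rate_hz: int = 16_000
    crop_s: float = 3.0
    preemph_coef: float = 0.97
    frame_len: int = 512
    hop: int = 160
    n_mels: int = 80
    apply_dct: bool = False

    def build(self) -> FeatureConfig:
        return FeatureConfig(**self.model_dump())


class BlockSection(_Strict):
    kernel_size: int
    out_channels: int
    pool: int
    reduction: int = 4


class ModelSection(_Strict):
    in_channels: int = 80
    blocks: list[BlockSection] | None = None
    n_classes: int = 4
    combine: str = "sum"
    activation: str = "sigmoid"
    use_channel_att: bool = True
    use_time_att: bool = True
    use_skip: bool = True

    def build(self) -> NetworkSpec:
        defaults = NetworkSpec()
        blocks = (
            tuple(RMAMSpec(**b.model_dump()) for b in self.blocks)
            if self.blocks
            else defaults.blocks
        )
        return NetworkSpec(
            in_channels=self.in_channels,
            blocks=blocks,
            n_classes=self.n_classes,
            combine=self.combine,
            activation=self.activation,
            use_channel_att=self.use_channel_att,
            use_time_att=self.use_time_att,
            use_skip=self.use_skip,
        )


class TrainSection(_Strict):
    epochs: int = 12
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


class SplitSection(_Strict):
    ratio: tuple[int, int] = (5, 1)
    segment_s: float = 5.0


class PathsSection(_Strict):
    corpus_dir: str = "corpus"
    checkpoint: str = "rmamnet.npz"
    report: str = "report.json"


class PipelineConfig(_Strict):
    corpus: CorpusSection = Field(default_factory=CorpusSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    split: SplitSection = Field(default_factory=SplitSection)
    paths: PathsSection = Field(default_factory=PathsSection)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; ``None`` gives defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return PipelineConfig.model_validate(raw)
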