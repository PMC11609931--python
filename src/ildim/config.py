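"""Model and training configuration.

Flat dataclasses mirroring the YAML layout used by the CLI.  The reference
configuration is deliberately small (64x64 grayscale images, two conv
blocks, hidden size 20, d_model 64) so that experiments run at desk scale;
``ModelConfig.large_image()`` returns the large-image profile (224x224 RGB,
3->64 first conv) used only for parameter-count introspection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

MODALITIES = ("image", "series", "text")


@dataclass
class ImageEncoderConfig:
    in_channels: int = 1
    channels: tuple = (8, 16)
    kernel_size: int = 3


@dataclass
class SequenceEncoderConfig:
    channels: int = 4
    hidden_size: int = 20
    pooling: str = "mean"  # {"mean", "last"}


@dataclass
class TextEncoderConfig:
    vocab_size: int = 120
    heads: int = 4
    use_positional: bool = True
    score_scale: str = "sqrt_dk"  # {"sqrt_dk", "dk"}


@dataclass
class FusionConfig:
    heads: int = 4
    projection_nonlinearity: str = "tanh"  # {"tanh", "identity"}
    fuse_input: str = "mf"  # {"mf", "alpha"}


@dataclass
class ModelConfig:
    d_model: int = 64
    image_size: int = 64
    series_length: int = 32
    n_classes: int = 2
    modalities: tuple = MODALITIES
    image_encoder: ImageEncoderConfig = field(default_factory=ImageEncoderConfig)
    sequence_encoder: SequenceEncoderConfig = field(
        default_factory=SequenceEncoderConfig
    )
    text_encoder: TextEncoderConfig = field(default_factory=TextEncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def __post_init__(self):
        self.modalities = tuple(self.modalities)
        self.image_encoder.channels = tuple(self.image_encoder.channels)
        for name in self.modalities:
            if name not in MODALITIES:
                raise ValueError(f"unknown modality {name!r}")
        if not self.modalities:
            raise ValueError("at least one modality is required")
        for heads in (self.text_encoder.heads, self.fusion.heads):
            if self.d_model % heads != 0:
                raise ValueError(
                    f"head count {heads} must divide d_model={self.d_model}"
                )

    @classmethod
    def large_image(cls) -> "ModelConfig":
        """Large-image profile: 224x224 RGB input, 3->64 channel first conv."""
        return cls(
            image_size=224,
            image_encoder=ImageEncoderConfig(in_channels=3, channels=(64,)),
        )

    def with_modalities(self, modalities) -> "ModelConfig":
        cfg = copy_config(self)
        cfg.modalities = tuple(modalities)
        cfg.__post_init__()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, sub in (
            ("image_encoder", ImageEncoderConfig),
            ("sequence_encoder", SequenceEncoderConfig),
            ("text_encoder", TextEncoderConfig),
            ("fusion", FusionConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    epsilon: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def copy_config(cfg: ModelConfig) -> ModelConfig:
    return ModelConfig.from_dict(cfg.to_dict())


def load_model_config(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ModelConfig.from_dict(data)


def save_model_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True, default_flow_style=None)
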