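"""Single-file pipeline configuration.

Defaults are the study constants: 0.5–40 Hz order-4 Bessel bandpass,
bior wavelet drift removal below 0.5 Hz, theta/alpha/beta/gamma bands,
1-s non-overlapping windows, sequence length 8, Adam lr 1e-4 batch 32,
binarization threshold 5, score weights 0.3/0.4/0.3.  Any deviation from
these requires an explicit override in the config file.  All randomness
fans out from the single top-level ``seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .types import ConfigurationError


@dataclass
class SynthSection:
    n_channels: int = 32
    fs: float = 128.0
    duration: float = 16.0
    n_trials: int = 24
    effect: float = 3.0
    scheme: str = "four-class"
    band_amps: dict = field(default_factory=lambda: {"theta": 10.0, "alpha": 10.0, "beta": 10.0, "gamma": 10.0})
    drift_amp: float = 20.0
    drift_freq: float = 0.1
    noise_sd: float = 5.0


@dataclass
class PreprocessSection:
    low: float = 0.5
    high: float = 40.0
    order: int = 4
    wavelet: str = "bior3.3"
    drift_cut: float = 0.5
    taper: str = "raised-cosine"


@dataclass
class FeatureSection:
    seq_len: int = 8
    band_order: int = 4
    smooth_k: int = 3
    grid: list | None = None  # null → smallest covering square


@dataclass
class ModelSection:
    conv1_out: int = 24
    conv2_out: int = 128
    fc1_out: int = 96
    embed_dim: int = 16
    lstm_hidden: int = 16
    bidirectional: bool = True
    attention_dim: int | None = None
    ablation: str = "full"


@dataclass
class TrainSection:
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 500
    split: str = "ratio-6:2:2"


@dataclass
class ScoreSection:
    threshold: float = 5.0
    weights: dict = field(default_factory=lambda: {"V": 0.3, "A": 0.4, "D": 0.3})
    n_windows: int = 60
    profile: str = "novelty-decay"


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "eegemo_run"
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    features: FeatureSection = field(default_factory=FeatureSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    score: ScoreSection = field(default_factory=ScoreSection)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {
            "synth": SynthSection,
            "preprocess": PreprocessSection,
            "features": FeatureSection,
            "model": ModelSection,
            "train": TrainSection,
            "score": ScoreSection,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sections:
                known = sections[key].__dataclass_fields__
                unknown = set(val) - set(known)
                if unknown:
                    raise ConfigurationError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                kwargs[key] = sections[key](**val)
            elif key in ("seed", "outdir"):
                kwargs[key] = val
            else:
                raise ConfigurationError(f"unknown config section {key!r}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
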