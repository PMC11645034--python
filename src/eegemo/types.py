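"""Core container types shared across the pipeline.

The pipeline's entry object is :class:`RawEEG`, a channels × samples matrix
with a sampling rate.  Band decomposition produces a :class:`BandedSignal`
(one filtered copy per rhythm band), and feature extraction assembles a
:class:`FeatureVolume`: a 4-D array of windowed differential-entropy values
laid out as (samples, bands, grid height, grid width) with aligned labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


class ValidationError(ValueError):
    """Raised when runtime data violates a contract (shape, range, NaN)."""


@dataclass
class RawEEG:
    """Multichannel EEG: ``data`` is channels × samples in microvolts."""

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(f"EEG data must be 2-D (channels × samples), got ndim={self.data.ndim}")
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValidationError("number of channel names does not match number of channels")
        bad = [n for n, row in zip(self.ch_names, self.data) if not np.all(np.isfinite(row))]
        if bad:
            raise ValidationError(f"non-finite samples in channels: {bad}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "RawEEG":
        return RawEEG(data=np.asarray(data, dtype=np.float64), fs=self.fs, ch_names=list(self.ch_names))


@dataclass
class BandedSignal:
    """Per-band zero-phase filtered copies of one :class:`RawEEG`."""

    bands: Mapping[str, RawEEG]
    order: list[str]

    def __iter__(self):
        return iter(self.order)

    def __getitem__(self, name: str) -> RawEEG:
        return self.bands[name]


@dataclass
class FeatureVolume:
    """(s, c, h, w) stack of per-window differential-entropy grids.

    ``data[s, c]`` is the h × w electrode grid of band ``c``'s DE values for
    window ``s``; unused grid cells are zero.  ``labels`` is aligned with
    the first axis.  ``layout`` records the 1D→2D mapping rule so the grid
    can be inverted back to the channel vector.
    """

    data: np.ndarray
    labels: np.ndarray
    layout: dict

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 4:
            raise ValidationError(f"feature volume must be 4-D (s, c, h, w), got ndim={self.data.ndim}")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError(
                f"labels ({len(self.labels)}) not aligned with samples ({self.data.shape[0]})"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]


@dataclass
class LabeledDataset:
    """Synthetic trials with per-trial ratings or class ids."""

    trials: list[RawEEG]
    ratings: np.ndarray
    scheme: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings)
        if len(self.ratings) != len(self.trials):
            raise ValidationError("one rating per trial required")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class VADScoreRecord:
    """One scored analysis window: VAD triple, aggregate score, state."""

    window: int
    V: float
    A: float
    D: float
    score: float
    state: str


Array = np.ndarray
Floats = Sequence[float]
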