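"""Band decomposition, differential-entropy features, labels, 3-D assembly.

The feature is the per-window, per-band, per-channel differential entropy
DE = ½·ln(2πeσ²), computed after zero-phase band filtering into the four
canonical rhythms (theta 4–8, alpha 8–14, beta 14–31, gamma 31–45 Hz).
For a band-limited oscillation the window variance σ² tracks band power,
so DE is a log-power feature: scaling the signal by c shifts DE by ln|c|.

Per-window channel vectors are placed row-major into a square electrode
grid, the four band grids are stacked as feature-map channels, and
consecutive windows are grouped into length-L sequences for the recurrent
classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import BesselBandpass, WindowPlan, design_bessel_bandpass, segment, zero_phase_filter
from .synth import DEFAULT_BAND_EDGES
from .types import BandedSignal, ConfigurationError, FeatureVolume, RawEEG, ValidationError

#: variance floor for degenerate (constant) windows
DE_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(f"band {self.name}: low must be < high")


DEFAULT_BANDS: list[BandSpec] = [BandSpec(name, lo, hi) for name, (lo, hi) in DEFAULT_BAND_EDGES.items()]


def band_decompose(
    x: RawEEG, bands: list[BandSpec] | None = None, order: int = 4
) -> BandedSignal:
    """Zero-phase Bessel bandpass into each rhythm band, same shape per band."""
    if bands is None:
        bands = DEFAULT_BANDS
    out = {}
    for b in bands:
        if b.high >= x.fs / 2:
            raise ConfigurationError(
                f"band {b.name} upper edge {b.high} Hz at/above Nyquist ({x.fs / 2} Hz)"
            )
        filt = design_bessel_bandpass(b.low, b.high, order=order, fs=x.fs)
        out[b.name] = zero_phase_filter(x, filt)
    return BandedSignal(bands=out, order=[b.name for b in bands])


def differential_entropy(window: np.ndarray, var_floor: float = DE_VAR_FLOOR) -> float:
    """DE = ½·ln(2πe·σ²) in nats, σ² the unbiased sample variance.

    The variance is floored at ``var_floor`` so constant windows map to a
    large negative finite value instead of −∞.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be a 1-D sequence of length >= 2")
    var = max(float(np.var(window, ddof=1)), var_floor)
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def _de_along_last(wins: np.ndarray, var_floor: float = DE_VAR_FLOOR) -> np.ndarray:
    var = np.maximum(wins.var(axis=-1, ddof=1), var_floor)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def extract_features(
    x: RawEEG,
    plan: WindowPlan | None = None,
    bands: list[BandSpec] | None = None,
    order: int = 4,
) -> np.ndarray:
    """Windowed DE table shaped (n_windows, n_bands, n_channels).

    Band filtering runs on the continuous signal; the taper is applied at
    segmentation, before the per-window variance.
    """
    if plan is None:
        plan = WindowPlan.one_second(x.fs)
    if bands is None:
        bands = DEFAULT_BANDS
    banded = band_decompose(x, bands, order=order)
    per_band = []
    for name in banded.order:
        wins = segment(banded[name], plan)       # (nw, C, win_len)
        per_band.append(_de_along_last(wins))    # (nw, C)
    return np.stack(per_band, axis=1)            # (nw, n_bands, C)


@dataclass
class LabelRule:
    """How per-trial ratings become per-window training labels."""

    mode: str = "binary-threshold"
    threshold: float = 5.0
    n_classes: int = 4
    # a rating strictly above the threshold is positive; the threshold
    # itself is negative (configurable via `at_threshold_positive`)
    at_threshold_positive: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("binary-threshold", "one-hot"):
            raise ConfigurationError(f"unknown label mode {self.mode!r}")
        if not 0 <= self.threshold <= 9:
            raise ConfigurationError("threshold must lie in the 0–9 rating range")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")


def make_labels(ratings: np.ndarray, rule: LabelRule, n_windows_per_trial: int) -> np.ndarray:
    """Expand per-trial ratings to per-window labels.

    Binary mode: label 1 iff rating > threshold (strict), then each trial's
    label replicated across its windows.  One-hot mode: class ids become
    length-``n_classes`` indicator rows, replicated likewise.
    """
    ratings = np.asarray(ratings)
    if n_windows_per_trial < 1:
        raise ValidationError("n_windows_per_trial must be >= 1")
    if rule.mode == "binary-threshold":
        r = ratings.astype(np.float64)
        if np.any(r < 0) or np.any(r > 9):
            raise ValidationError("ratings outside the 0–9 range")
        pos = (r >= rule.threshold) if rule.at_threshold_positive else (r > rule.threshold)
        labels = pos.astype(np.int64)
    else:
        k = ratings.astype(np.int64)
        if np.any(k < 0) or np.any(k >= rule.n_classes):
            raise ValidationError(f"class ids outside 0..{rule.n_classes - 1}")
        labels = np.eye(rule.n_classes, dtype=np.int64)[k]
    return np.repeat(labels, n_windows_per_trial, axis=0)


def grid_shape(n_channels: int) -> tuple[int, int]:
    """Smallest square grid covering n_channels (6×6 for 32, 3×3 for 8)."""
    side = math.isqrt(n_channels)
    if side * side < n_channels:
        side += 1
    return side, side


def to_grid(values: np.ndarray, layout: tuple[int, int] | None = None) -> np.ndarray:
    """Row-major placement of consecutive channels into an h × w grid.

    Unused trailing cells are zero; the used cells are invertible by
    flattening row-major and truncating.
    """
    values = np.asarray(values, dtype=np.float64)
    h, w = layout if layout is not None else grid_shape(values.shape[-1])
    n = values.shape[-1]
    if h * w < n:
        raise ConfigurationError(f"grid {h}×{w} too small for {n} channels")
    pad = np.zeros(values.shape[:-1] + (h * w,))
    pad[..., :n] = values
    return pad.reshape(values.shape[:-1] + (h, w))


def from_grid(grid: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of :func:`to_grid` restricted to the used cells."""
    return grid.reshape(grid.shape[:-2] + (-1,))[..., :n_channels]


def assemble_volume(
    features: np.ndarray, labels: np.ndarray, layout: tuple[int, int] | None = None
) -> FeatureVolume:
    """Stack per-band electrode grids into an (s, c, h, w) volume.

    Window order (the time axis) is preserved so sequences can be cut for
    the recurrent model; the feature-map channel axis c follows the band
    order of ``features``.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3:
        raise ValidationError("features must be (n_windows, n_bands, n_channels)")
    labels = np.asarray(labels)
    if len(labels) != features.shape[0]:
        raise ValidationError(
            f"labels ({len(labels)}) misaligned with windows ({features.shape[0]})"
        )
    n_channels = features.shape[2]
    h, w = layout if layout is not None else grid_shape(n_channels)
    data = to_grid(features, (h, w))
    return FeatureVolume(
        data=data,
        labels=labels,
        layout={"rule": "row-major", "h": h, "w": w, "n_channels": n_channels},
    )


def group_sequences(volume: FeatureVolume, L: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Group consecutive windows into length-L sequences.

    Returns (sequences, labels): sequences (n_seq, L, c, h, w); each
    sequence's label is taken from its first window (callers segment
    per-trial data, where all windows share the trial label).  The trailing
    remainder of windows that does not fill a sequence is dropped.
    """
    if L < 1:
        raise ConfigurationError("sequence length L must be >= 1")
    s = volume.n_samples
    n_seq = s // L
    if n_seq == 0:
        raise ValidationError(f"not enough windows ({s}) for one length-{L} sequence")
    data = volume.data[: n_seq * L].reshape((n_seq, L) + volume.data.shape[1:])
    labels = volume.labels[: n_seq * L : L]
    return data, np.asarray(labels)


def save_volume(path, volume: FeatureVolume) -> None:
    import json

    np.savez(path, data=volume.data, labels=volume.labels, layout=json.dumps(volume.layout))


def load_volume(path) -> FeatureVolume:
    import json

    with np.load(path, allow_pickle=False) as z:
        return FeatureVolume(data=z["data"], labels=z["labels"], layout=json.loads(str(z["layout"])))


def features_to_table(features: np.ndarray, band_names: list[str] | None = None):
    """Flat (window, band, channel, DE) DataFrame for CSV export."""
    import pandas as pd

    if band_names is None:
        band_names = [b.name for b in DEFAULT_BANDS]
    nw, nb, nc = features.shape
    wi, bi, ci = np.meshgrid(np.arange(nw), np.arange(nb), np.arange(nc), indexing="ij")
    return pd.DataFrame(
        {
            "window": wi.ravel(),
            "band": np.asarray(band_names)[bi.ravel()],
            "channel": ci.ravel(),
            "de": features.ravel(),
        }
    )
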