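"""Signal conditioning.

Order of operations in the standard pipeline:

1. wavelet baseline-drift removal (:func:`remove_baseline`) — multilevel
   biorthogonal decomposition, zero the deepest approximation coefficients
   (the sub-0.5 Hz drift carrier), reconstruct;
2. zero-phase Bessel bandpass 0.5–40 Hz (:func:`design_bessel_bandpass` +
   :func:`zero_phase_filter`) — the Bessel family is chosen for its nearly
   constant passband group delay, and the forward–backward application
   cancels the remaining phase so waveform timing is preserved;
3. segmentation into tapered windows (:func:`segment`), 1 s non-overlapping
   by default;
4. optional moving-average smoothing of feature series
   (:func:`moving_average`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .types import ConfigurationError, RawEEG, ValidationError

__all__ = [
    "bessel_poly_coeffs",
    "BesselBandpass",
    "design_bessel_bandpass",
    "zero_phase_filter",
    "WaveletConfig",
    "remove_baseline",
    "hamming_window",
    "WindowPlan",
    "segment",
    "moving_average",
    "frequency_response_table",
]


def bessel_poly_coeffs(n: int) -> list[int]:
    """Exact integer coefficients a_0..a_n of the reverse Bessel polynomial.

    B_n(s) = sum_k a_k s^k with a_k = (2n−k)! / (k! (n−k)! 2^{n−k}) and
    a_n = 1.  These polynomials appear in the denominator of the Bessel
    filter transfer function T_n(s) = B_n(0)/B_n(s).
    """
    if not isinstance(n, (int, np.integer)) or n < 0:
        raise ValueError(f"order must be a non-negative integer, got {n!r}")
    return [
        math.factorial(2 * n - k) // (math.factorial(k) * math.factorial(n - k) * 2 ** (n - k))
        for k in range(n + 1)
    ]


@dataclass
class BesselBandpass:
    """A realized zero-phase-capable Bessel bandpass filter.

    ``sos`` holds second-order sections of the magnitude-normalized design:
    single-pass magnitude is −3 dB at ``low`` and ``high``.
    """

    order: int
    low: float
    high: float
    fs: float
    sos: np.ndarray

    def magnitude_db(self, freqs: np.ndarray) -> np.ndarray:
        """Single-pass magnitude response in dB at the given frequencies."""
        _, h = sps.sosfreqz(self.sos, worN=np.atleast_1d(np.asarray(freqs, float)), fs=self.fs)
        return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))

    def group_delay(self, freqs: np.ndarray) -> np.ndarray:
        """Single-pass group delay in samples at the given frequencies."""
        b, a = sps.sos2tf(self.sos)
        w, gd = sps.group_delay((b, a), w=np.atleast_1d(np.asarray(freqs, float)), fs=self.fs)
        return gd


def design_bessel_bandpass(low: float, high: float, order: int = 4, fs: float = 128.0) -> BesselBandpass:
    """Design a magnitude-normalized Bessel bandpass (−3 dB at both edges).

    Default analysis band in the pipeline is 0.5–40 Hz at order 4.
    """
    if order < 1:
        raise ConfigurationError("order must be >= 1")
    if not (0 < low < high < fs / 2):
        raise ConfigurationError(
            f"band edges must satisfy 0 < low < high < fs/2; got low={low}, high={high}, fs={fs}"
        )
    sos = sps.bessel(order, [low, high], btype="bandpass", norm="mag", fs=fs, output="sos")
    z, p, _ = sps.sos2zpk(sos)
    if np.any(np.abs(p) >= 1.0):
        raise ConfigurationError("designed filter is unstable (pole on/outside unit circle)")
    return BesselBandpass(order=order, low=low, high=high, fs=fs, sos=sos)


def zero_phase_filter(x: RawEEG, f: BesselBandpass) -> RawEEG:
    """Forward–backward (zero-phase) application of ``f`` to every channel.

    Output length equals input length; in-band sinusoids incur no net phase
    shift; stop-band attenuation doubles in dB relative to a single pass.
    """
    min_len = 3 * (2 * f.order) + 1
    if x.n_samples <= min_len:
        raise ValidationError(
            f"signal too short for zero-phase filtering: {x.n_samples} samples, need > {min_len}"
        )
    y = sps.sosfiltfilt(f.sos, x.data, axis=1)
    return x.copy_with(y)


@dataclass
class WaveletConfig:
    """Multilevel wavelet decomposition plan for baseline-drift removal.

    ``family`` is a biorthogonal identifier ``"biorX.Y"`` (X reconstruction
    order, Y decomposition order).  ``levels=None`` selects the smallest L
    with fs/2^(L+1) <= drift_cut, i.e. the deepest approximation band lies
    entirely inside the drift range.
    """

    family: str = "bior3.3"
    levels: int | None = None
    drift_cut: float = 0.5

    def __post_init__(self) -> None:
        if self.drift_cut <= 0:
            raise ConfigurationError("drift_cut must be positive")
        if self.levels is not None and self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        supported = pywt.wavelist("bior")
        if self.family not in supported:
            raise ConfigurationError(
                f"unsupported wavelet {self.family!r}; supported biorthogonal bases: {supported}"
            )

    def resolve_levels(self, fs: float, n_samples: int | None = None) -> int:
        if self.levels is not None:
            if fs / 2**self.levels > self.drift_cut * 2:
                raise ConfigurationError(
                    f"levels={self.levels} leaves the approximation band above drift_cut={self.drift_cut} Hz"
                )
            return self.levels
        L = 1
        while fs / 2 ** (L + 1) > self.drift_cut:
            L += 1
        if n_samples is not None:
            # cap at the depth the signal supports without dominant boundary effects
            cap = pywt.dwt_max_level(n_samples, pywt.Wavelet(self.family).dec_len)
            if cap < 1:
                raise ConfigurationError(f"signal too short ({n_samples}) for wavelet {self.family}")
            L = min(L, cap)
        return L


def remove_baseline(x: RawEEG, w: WaveletConfig | None = None) -> RawEEG:
    """Remove sub-``drift_cut`` baseline drift by wavelet reconstruction.

    Decomposes each channel with the configured biorthogonal basis, zeroes
    the deepest approximation coefficients (which carry the drift), keeps
    every detail level untouched, and reconstructs to the original length.
    """
    if w is None:
        w = WaveletConfig()
    levels = w.resolve_levels(x.fs, x.n_samples)
    if x.n_samples < 2**levels:
        raise ValidationError(f"signal length {x.n_samples} < 2^levels = {2**levels}")
    coeffs = pywt.wavedec(x.data, w.family, level=levels, axis=1)
    coeffs[0] = np.zeros_like(coeffs[0])
    y = pywt.waverec(coeffs, w.family, axis=1)
    return x.copy_with(y[:, : x.n_samples])


def hamming_window(M: int, variant: str = "raised-cosine") -> np.ndarray:
    """Length-M taper ω(n) = 0.5·[1 − cos(2πn/(M−1))] for 0 ≤ n ≤ M−1.

    The 0.5/0.5 raised-cosine form is the default; ``variant="hamming"``
    switches to the 0.54 − 0.46·cos form.  Outside [0, M−1] the window is
    defined as zero (windows are finite-support by construction).
    """
    if M < 2:
        raise ValueError(f"window length must be >= 2, got {M}")
    n = np.arange(M)
    if variant == "raised-cosine":
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (M - 1)))
    if variant == "hamming":
        return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (M - 1))
    raise ConfigurationError(f"unknown taper variant {variant!r}")


@dataclass
class WindowPlan:
    """Segmentation plan: window length, hop, and taper weights."""

    win_len: int
    hop: int | None = None
    taper: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.win_len < 2:
            raise ConfigurationError("win_len must be >= 2 samples")
        if self.hop is None:
            self.hop = self.win_len  # no overlap
        if self.hop < 1:
            raise ConfigurationError("hop must be >= 1")
        if self.taper is None:
            self.taper = hamming_window(self.win_len)
        self.taper = np.asarray(self.taper, dtype=np.float64)
        if len(self.taper) != self.win_len:
            raise ConfigurationError("taper length must equal win_len")

    @classmethod
    def one_second(cls, fs: float) -> "WindowPlan":
        """The pipeline default: 1-s windows, no overlap, tapered."""
        return cls(win_len=int(round(fs)))

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.win_len:
            return 0
        return 1 + (n_samples - self.win_len) // self.hop


def segment(x: RawEEG, plan: WindowPlan) -> np.ndarray:
    """Cut into tapered windows: (n_windows, n_channels, win_len).

    A trailing partial window is dropped.
    """
    if plan.win_len > x.n_samples:
        raise ValidationError(f"win_len={plan.win_len} exceeds signal length {x.n_samples}")
    nw = plan.n_windows(x.n_samples)
    idx = np.arange(plan.win_len)[None, :] + plan.hop * np.arange(nw)[:, None]
    wins = x.data[:, idx]              # (C, nw, win_len)
    wins = np.moveaxis(wins, 0, 1)     # (nw, C, win_len)
    return wins * plan.taper[None, None, :]


def moving_average(series: np.ndarray, k: int = 3) -> np.ndarray:
    """Centered moving mean along axis 0 with edge truncation.

    ``k`` must be odd; near the edges the mean is taken over the available
    part of the window, so output length equals input length and a
    constant series is unchanged.
    """
    series = np.asarray(series, dtype=np.float64)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    if k > len(series):
        raise ValueError(f"k={k} larger than series length {len(series)}")
    if k == 1:
        return series.copy()
    half = k // 2
    csum = np.cumsum(series, axis=0)
    zero = np.zeros((1,) + series.shape[1:])
    csum = np.concatenate([zero, csum], axis=0)
    n = len(series)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    sums = csum[hi] - csum[lo]
    counts = (hi - lo).reshape((-1,) + (1,) * (series.ndim - 1))
    return sums / counts


def frequency_response_table(f: BesselBandpass, n_points: int = 512) -> np.ndarray:
    """(frequency Hz, magnitude dB, group delay samples) rows for audit export."""
    freqs = np.linspace(0.01, f.fs / 2 * 0.999, n_points)
    return np.column_stack([freqs, f.magnitude_db(freqs), f.group_delay(freqs)])
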