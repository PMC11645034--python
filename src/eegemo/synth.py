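"""Synthetic EEG generator.

Real scalp EEG is a superposition of band-limited oscillations (theta,
alpha, beta, gamma rhythms, amplitudes in the 0–60 µV range), slow
electrode/physiology baseline drift well below the analysis passband, and
broadband noise.  This module emulates exactly those three ingredients so
that every downstream stage — drift removal, band decomposition,
differential-entropy features, the classifier — can be exercised and tested
without access to recorded data.

Class structure is injected multiplicatively on band amplitudes: a class
effect ``e`` on band ``b`` multiplies that band's oscillator amplitude,
which shifts the band's differential entropy by ``ln e`` (DE of a Gaussian
window is ½ln(2πeσ²)), giving an analyzable learnability handle.

Emulated label schemes:

* ``"vad-binary"`` — continuous 0–9 valence/arousal/dominance ratings, one
  triple per trial; a rating above 5 on a dimension co-occurs with a boost
  of that dimension's designated band (valence→alpha, arousal→beta,
  dominance→gamma).
* ``"four-class"`` — discrete labels 0..3; class k boosts band k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import ConfigurationError, LabeledDataset, RawEEG

#: band name → (low, high) Hz; canonical EEG rhythm edges used pipeline-wide
DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 31.0),
    "gamma": (31.0, 45.0),
}

#: VAD dimension → band whose amplitude it modulates in "vad-binary" data
VAD_BAND_MAP = {"V": "alpha", "A": "beta", "D": "gamma"}


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG model.

    Defaults describe a plausible resting-state montage: 32 channels at
    128 Hz, 10 µV rhythm oscillators, a 20 µV drift at 0.1 Hz (far below
    the 0.5 Hz high-pass edge, so it is removable by design) and 5 µV
    white noise.
    """

    n_channels: int = 32
    fs: float = 128.0
    duration: float = 60.0
    band_amps: dict[str, float] = field(
        default_factory=lambda: {"theta": 10.0, "alpha": 10.0, "beta": 10.0, "gamma": 10.0}
    )
    drift_amp: float = 20.0
    drift_freq: float = 0.1
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")
        unknown = set(self.band_amps) - set(DEFAULT_BAND_EDGES)
        if unknown:
            raise ConfigurationError(f"unknown bands in band_amps: {sorted(unknown)}")
        active = [b for b, a in self.band_amps.items() if a > 0]
        if active:
            top = max(DEFAULT_BAND_EDGES[b][1] for b in active)
            if self.fs <= 2 * top:
                raise ConfigurationError(
                    f"fs={self.fs} violates Nyquist safety for highest active band edge {top} Hz"
                )
        if self.drift_amp > 0 and not self.drift_freq < 0.5:
            raise ConfigurationError("drift_freq must be < 0.5 Hz so drift lies below the passband")


def _synth_trial(cfg: SynthConfig, rng: np.random.Generator, envelopes: dict | None = None) -> RawEEG:
    """Band sinusoids (optionally amplitude-modulated) + drift + noise."""
    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    data = np.zeros((cfg.n_channels, n))
    for band, amp in cfg.band_amps.items():
        lo, hi = DEFAULT_BAND_EDGES[band]
        freqs = rng.uniform(lo, hi, size=cfg.n_channels)
        phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
        if amp != 0:
            comp = amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
            if envelopes and band in envelopes:
                comp = comp * envelopes[band][None, :]
            data += comp
    if cfg.drift_amp != 0:
        phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
        data += cfg.drift_amp * np.sin(2 * np.pi * cfg.drift_freq * t[None, :] + phases[:, None])
    if cfg.noise_sd != 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    return RawEEG(data=data, fs=cfg.fs)


def gen_raw_eeg(cfg: SynthConfig) -> RawEEG:
    """Generate one synthetic EEG trial.

    Each channel is a sum of one sinusoid per band (frequency drawn
    uniformly inside the band, independent random phase per channel per
    band), a common-frequency drift sinusoid with per-channel phase, and
    white Gaussian noise.  Identical config (including seed) gives a
    bit-identical matrix.
    """
    return _synth_trial(cfg, np.random.default_rng(cfg.seed))


def _spread(n_trials: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced group assignment (counts differ by at most 1), shuffled."""
    base = np.arange(n_trials) % n_groups
    rng.shuffle(base)
    return base


def _burst_envelope(
    cfg: SynthConfig, effect: float, burst_fraction: float, window_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Per-sample envelope boosting ``effect``× in a random subset of windows."""
    n = int(round(cfg.fs * cfg.duration))
    wlen = int(round(cfg.fs * window_s))
    n_win = max(n // wlen, 1)
    mask = rng.random(n_win) < burst_fraction
    env = np.ones(n)
    for wi in np.flatnonzero(mask):
        env[wi * wlen : (wi + 1) * wlen] = effect
    return env, mask.astype(int).tolist()


def gen_labeled_dataset(
    n_trials: int,
    effect: float,
    scheme: str,
    cfg: SynthConfig | None = None,
    burst_fraction: float | None = None,
    window_s: float = 1.0,
) -> LabeledDataset:
    """Generate a labeled trial set with class-conditional band power.

    ``effect`` multiplies the designated band's oscillator amplitude for
    the boosted condition; ``effect=1`` produces null data with no class
    signal.  Labels are balanced to within one trial.

    With ``burst_fraction`` set, the boost is *sequence-structured*: it is
    active only in a random Bernoulli(``burst_fraction``) subset of the
    trial's ``window_s``-second analysis windows, so only those windows
    carry class information.  The per-trial informative-window masks are
    recorded in ``metadata["window_informative"]`` (used to verify that
    attention concentrates on informative time steps).
    """
    if cfg is None:
        cfg = SynthConfig()
    if effect < 1:
        raise ConfigurationError("effect must be >= 1")
    if n_trials < 2:
        raise ConfigurationError("n_trials must be >= 2")
    if scheme not in ("vad-binary", "four-class"):
        raise ConfigurationError(f"unknown scheme {scheme!r}; use 'vad-binary' or 'four-class'")
    if burst_fraction is not None and not 0 < burst_fraction <= 1:
        raise ConfigurationError("burst_fraction must lie in (0, 1]")

    rng = np.random.default_rng(cfg.seed)
    band_order = list(DEFAULT_BAND_EDGES)
    trials: list[RawEEG] = []
    masks: list[list[int]] = []

    def build(boosted: list[str]) -> RawEEG:
        sub_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        if burst_fraction is None:
            amps = dict(cfg.band_amps)
            for band in boosted:
                amps[band] = amps.get(band, 0.0) * effect
            return _synth_trial(replace(cfg, band_amps=amps), sub_rng)
        env, mask = _burst_envelope(cfg, effect, burst_fraction, window_s, sub_rng)
        masks.append(mask if boosted else [0] * len(mask))
        return _synth_trial(cfg, sub_rng, envelopes={band: env for band in boosted})

    if scheme == "four-class":
        labels = _spread(n_trials, 4, rng)
        for k in labels:
            trials.append(build([band_order[int(k)]]))
        ratings = labels.astype(np.int64)
    else:
        # one independent high/low condition per VAD dimension, balanced
        high = np.stack([_spread(n_trials, 2, rng) for _ in range(3)], axis=1).astype(bool)
        ratings = np.empty((n_trials, 3))
        for i in range(n_trials):
            boosted = []
            for d, dim in enumerate(("V", "A", "D")):
                if high[i, d]:
                    ratings[i, d] = max(rng.uniform(5.0, 9.0), np.nextafter(5.0, 9.0))
                    boosted.append(VAD_BAND_MAP[dim])
                else:
                    ratings[i, d] = rng.uniform(0.0, 5.0)
            trials.append(build(boosted))

    meta = {
        "scheme": scheme,
        "effect": effect,
        "n_trials": n_trials,
        "fs": cfg.fs,
        "duration": cfg.duration,
        "seed": cfg.seed,
    }
    if burst_fraction is not None:
        meta["burst_fraction"] = burst_fraction
        meta["window_informative"] = masks
    return LabeledDataset(trials=trials, ratings=ratings, scheme=scheme, metadata=meta)


def gen_vad_stream(
    n_windows: int,
    profile: str = "novelty-decay",
    seed: int = 0,
    noise_sd: float = 0.3,
) -> np.ndarray:
    """Generate an (n_windows, 3) sequence of VAD triples in [0, 9].

    ``"novelty-decay"`` emulates a learner whose engagement starts high and
    wanes over the session: the expected score decays linearly from ~7 to
    ~3.5, so the aggregate learning score crosses the 5-point line partway
    through.  ``"flat"`` holds the expectation constant at 5.
    """
    if n_windows < 1:
        raise ConfigurationError("n_windows must be >= 1")
    if profile not in ("novelty-decay", "flat"):
        raise ConfigurationError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    if profile == "flat":
        base = np.full(n_windows, 5.0)
    else:
        base = np.linspace(7.0, 3.5, n_windows)
    vad = base[:, None] + rng.normal(0.0, noise_sd, size=(n_windows, 3)) if noise_sd else np.repeat(
        base[:, None], 3, axis=1
    )
    return np.clip(vad, 0.0, 9.0)
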