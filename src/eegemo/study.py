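"""Desk-scale study protocol: generate → condition → featurize → train → score.

Bundles the full experimental chain at the library level (the CLI drives
the same stages through file artifacts) so the study can be reproduced in
one call.  Default problem size: 80 trials × 40 s at 128 Hz, 32 channels,
giving 400 length-8 sequences — small enough for a CPU, large enough for
stable accuracy estimates.
"""

from __future__ import annotations

import numpy as np

from . import preprocess as pre
from . import synth
from .features import assemble_volume, extract_features, group_sequences
from .model import ClassifierConfig, build_model
from .train import EvalReport, TrainConfig, evaluate, fit, split_data


def prepare_fourclass_features(
    n_trials: int = 80,
    duration: float = 40.0,
    effect: float = 3.0,
    seed: int = 0,
    n_channels: int = 32,
    fs: float = 128.0,
    seq_len: int = 8,
    burst_fraction: float | None = None,
    smooth_k: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Four-class DE sequences through the full conditioning chain.

    Returns (X, y, trial_ids) with X shaped (n_seq, L, bands, h, w).
    """
    cfg = synth.SynthConfig(n_channels=n_channels, fs=fs, duration=duration, seed=seed)
    ds = synth.gen_labeled_dataset(n_trials, effect, "four-class", cfg, burst_fraction=burst_fraction)
    wcfg = pre.WaveletConfig()
    bp = pre.design_bessel_bandpass(0.5, 40.0, 4, fs)
    plan = pre.WindowPlan.one_second(fs)
    Xs, ys, tids = [], [], []
    for ti, trial in enumerate(ds.trials):
        clean = pre.zero_phase_filter(pre.remove_baseline(trial, wcfg), bp)
        table = extract_features(clean, plan)
        if smooth_k > 1 and len(table) >= smooth_k:
            table = pre.moving_average(table, smooth_k)
        vol = assemble_volume(table, np.repeat(int(ds.ratings[ti]), len(table)))
        X, y = group_sequences(vol, seq_len)
        Xs.append(X)
        ys.append(y)
        tids.append(np.full(len(X), ti))
    return np.concatenate(Xs), np.concatenate(ys), np.concatenate(tids)


def train_variant(
    X: np.ndarray,
    y: np.ndarray,
    variant: str = "full",
    epochs: int = 200,
    seed: int = 0,
    lr: float = 1e-4,
) -> tuple[EvalReport, dict]:
    """Train one architecture variant on a contiguous 6:2:2 split."""
    tcfg = TrainConfig(lr=lr, epochs=epochs, seed=seed)
    tr, va, te = split_data(X, y, tcfg)
    n_classes = int(y.max()) + 1
    mcfg = ClassifierConfig(
        in_channels=X.shape[2], grid=tuple(X.shape[-2:]), n_classes=n_classes,
        seq_len=X.shape[1], ablation=variant,
    )
    model = build_model(mcfg, seed=seed)
    history = fit(model, tr, va, tcfg)
    return evaluate(model, te), history


def ablation_study(
    X: np.ndarray,
    y: np.ndarray,
    variants: tuple[str, ...] = ("full", "no_attention", "no_bilstm"),
    epochs: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Test accuracy (percent) per architecture variant, trained identically."""
    return {v: train_variant(X, y, v, epochs=epochs, seed=seed)[0].accuracy for v in variants}
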