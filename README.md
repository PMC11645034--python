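# eegemo

EEG emotion recognition and learning-effectiveness scoring, end to end and
fully testable on synthetic data.

The package is aimed at researchers who want a transparent, CPU-only
re-implementation of a common class of EEG emotion pipelines: condition the
raw signal, extract band-wise differential-entropy features, classify with
a convolutional/recurrent/attention network, and map predicted
valence–arousal–dominance (VAD) emotion ratings to an interpretable
learning-effectiveness score. Because public emotion corpora (DEAP-style
continuous 0–9 VAD ratings; SEED-IV-style four discrete emotions) cannot be
redistributed, the package ships a synthetic EEG generator that emulates
the statistical structure those datasets contribute: band-limited
oscillations (theta 4–8, alpha 8–14, beta 14–31, gamma 31–45 Hz) in the
0–60 µV range, sub-0.5 Hz baseline drift, broadband noise, and
class-conditional band-power effects.

## Pipeline

1. **Drift removal** — multilevel biorthogonal wavelet decomposition
   (default `bior3.3`), zero the deepest approximation coefficients (the
   sub-0.5 Hz drift carrier), reconstruct.
2. **Bandpass** — zero-phase (forward–backward) 4th-order Bessel filter,
   0.5–40 Hz, magnitude-normalized so both edges sit at −3 dB. The Bessel
   polynomial B_n(s) = Σ a_k s^k with a_k = (2n−k)!/(k!(n−k)!2^(n−k)) gives
   near-constant passband group delay, preserving waveform shape.
3. **Features** — 1-s non-overlapping windows with a raised-cosine taper
   ω(n) = 0.5·[1 − cos(2πn/(M−1))]; per window, per band, per channel the
   differential entropy DE = ½·ln(2πeσ²) of the band-filtered signal, a
   log-band-power feature (DE(c·x) = DE(x) + ln|c|).
4. **3-D assembly** — each window's per-channel DE vector is placed
   row-major into an h×w electrode grid; the four band grids stack into a
   (s, c, h, w) feature volume; consecutive windows form length-8
   sequences.
5. **Classifier** — per window: conv 4→24 (5×5, pad 2), 2×2 max-pool,
   conv 24→128 (2×2), FC 512→96, FC 96→16; a bidirectional LSTM (hidden 16
   per direction) over the 8-window sequence; scaled dot-product attention
   (softmax(q·Kᵀ/√d_k) with a learned query over the per-step hidden
   states) pools the sequence; a linear head emits class scores. Ablation
   variants (`no_attention`, `no_bilstm`, `neither`) re-wire the sequence
   stage for controlled comparisons. The network runs on a small
   reverse-mode autodiff engine built on NumPy (`eegemo.nn`) — no GPU or
   deep-learning framework required — trained with Adam (lr 1e-4, batch
   32) on cross-entropy.
6. **Scoring** — per-window VAD estimates combine into
   Score = 0.3·V + 0.4·A + 0.3·D on the 0–9 scale, classified into
   Ineffective [0,3), Moderate [3,4), Good [4,6), Excellent [6,9].

## Worked example

```python
import numpy as np
from eegemo import study

# 24 four-class trials, 24 s at 128 Hz, 32 channels, band-power effect 3x
X, y, _ = study.prepare_fourclass_features(n_trials=24, duration=24.0,
                                           effect=3.0, seed=5)
print("sequences:", X.shape, "labels:", np.bincount(y))
rep, hist = study.train_variant(X, y, "full", epochs=200, seed=0)
print(f"test accuracy: {rep.accuracy:.1f}%  macro-F1: {rep.f1:.3f}")
```

prints (about ten seconds on one CPU):

```
sequences: (72, 8, 4, 6, 6) labels: [18 18 18 18]
test accuracy: 100.0%  macro-F1: 1.000
```

The feature volume holds 72 sequences of 8 one-second windows, each window
a 4-band × 6×6-grid DE map; with a 3× band-power effect the classes are
cleanly separable and the network recovers them perfectly on the held-out
20% test block. Scoring a synthetic engagement stream:

```python
from eegemo import gen_vad_stream, stream_scores

report = stream_scores(gen_vad_stream(6, "novelty-decay", seed=3, noise_sd=0.0))
for r in report.records:
    print(f"window {r.window}: score {r.score:.2f} ({r.state})")
print("mean score:", round(report.mean_score, 3))
```

```
window 0: score 7.00 (Excellent)
window 1: score 6.30 (Excellent)
window 2: score 5.60 (Good)
window 3: score 4.90 (Good)
window 4: score 4.20 (Good)
window 5: score 3.50 (Moderate)
mean score: 5.25
```

— the novelty-decay profile emulates a learner whose engagement wanes over
a session, crossing the score-5 line partway through.

## Command line

The same stages run from the shell, chained through a run directory:

```sh
eegemo --seed 7 --out run simulate
eegemo --seed 7 --out run preprocess
eegemo --seed 7 --out run features
eegemo --seed 7 --out run train
eegemo --seed 7 --out run evaluate   # writes run/report.json, run/report.csv
eegemo --seed 7 --out run score      # writes run/scores.csv
```

Every stage updates `run/manifest.json` (config hash, seed, versions,
timings). Defaults follow the study constants (0.5–40 Hz order-4 Bessel,
threshold 5, weights 0.3/0.4/0.3, lr 1e-4, batch 32, sequence length 8);
overrides go in a YAML file passed via `--config`.

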