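# Methods

This note records the models, numerical choices, and open design decisions
behind the package, and what the synthetic experiments do and do not show.

## Signal model and generator

Scalp EEG is modelled as a superposition of narrow-band oscillations in the
four canonical rhythm bands (theta 4–8 Hz, alpha 8–14 Hz, beta 14–31 Hz,
gamma 31–45 Hz), a slow baseline drift, and broadband noise. The generator
(`eegemo.synth`) draws, per channel and band, one sinusoid with frequency
uniform inside the band and independent random phase (avoiding degenerate
inter-channel identity), adds a drift sinusoid below 0.5 Hz, and white
Gaussian noise. Defaults — 32 channels at 128 Hz, 10 µV band oscillators,
20 µV drift at 0.1 Hz, 5 µV noise — place amplitudes in the 0–60 µV range
typical of scalp recordings while keeping the drift strictly below the
analysis passband, so it is removable by construction.

Class structure is injected multiplicatively: a condition with effect *e*
multiplies the designated band's oscillator amplitude by *e*, which shifts
that band's differential entropy by exactly ln *e*. This makes
learnability analyzable — a band-power argmax oracle solves the task — but
it also means the class signal is **linear in the sequence-mean DE
features**. Two label schemes emulate the two public-corpus conventions:
continuous 0–9 VAD triples with each dimension's high condition (> 5)
boosting a designated band (valence→alpha, arousal→beta, dominance→gamma),
and four discrete classes, class *k* boosting band *k*. An optional
`burst_fraction` makes the boost *sequence-structured*: active only in a
Bernoulli subset of 1-s windows, with the informative-window masks recorded
so attention behaviour can be audited.

What the generator does **not** emulate: electrode-geometry forward models
and inter-channel correlation structure, non-sinusoidal artifacts
(EMG/EOG), 1/f background spectra, non-stationarity beyond the burst
envelope, and — most importantly — the nonlinear temporal emotion dynamics
of recorded EEG. Passing tests therefore demonstrate correctness of the
pipeline's mechanics and its behaviour under a controlled, analyzable
signal model; they are not evidence about accuracy on recorded data.

## Conditioning

**Drift removal.** Multilevel wavelet decomposition with a biorthogonal
basis; the deepest approximation coefficients (the drift carrier) are
zeroed, all detail coefficients are kept, and the signal is reconstructed
to its original length. The depth is the smallest L with
fs/2^(L+1) ≤ drift_cut (default 0.5 Hz), capped at the depth the signal
length supports, so the approximation band lies inside the drift range.
Zeroing only the approximation is deterministic and leaves in-band detail
untouched (alpha-band power changes < 5 × 10⁻⁵ % on synthetic alpha+drift
input); no detail thresholding is applied. The default basis is `bior3.3`:
the "bior4.3" naming with reconstruction order 4 and decomposition order 3
is not a member of the standard biorthogonal family, so the nearest
supported symmetric basis is used and any supported `biorX.Y` is accepted
in configuration.

**Bandpass.** 4th-order Bessel bandpass, 0.5–40 Hz, designed in
second-order sections with magnitude normalization (−3 dB at both edges —
the conventional half-power reading when only the band is stated) and
applied forward–backward (`sosfiltfilt`), so the net phase response is
zero and stop-band attenuation doubles in dB. Bessel rolloff is
deliberately gentle: 60 Hz at fs = 256 sits ≈ 9.8 dB down single-pass
(≈ 19.6 dB after two passes) — the family trades stop-band steepness for
time-domain fidelity. In the digital bandpass realization the analog
prototype's maximally flat group delay survives only approximately
(≈ 0.7-sample dispersion across 5–30 Hz at fs = 128, from the bandpass
transform and bilinear warping); the forward–backward application cancels
phase regardless, and tests assert the sub-sample absolute dispersion.

**Windowing.** 1-s non-overlapping windows; the taper implements the
raised-cosine form ω(n) = 0.5·[1 − cos(2πn/(M−1))] as the default (the
printed 0.5/0.5 coefficients are implemented as given, although that form
is conventionally named Hann rather than Hamming), with the 0.54/0.46
variant available by configuration. Feature-series smoothing uses a
centred moving average with edge truncation, default k = 3 windows — the
minimal smoothing that still tracks slow emotional dynamics — applied per
trial so smoothing never crosses trial boundaries.

## Features

Per window, band, and channel: DE = ½·ln(2πe·σ²) in nats with the unbiased
sample variance, floored at ε = 1e−12 so constant windows yield a large
negative finite value rather than −∞. For a Gaussian band-limited signal
this is the band's log power up to constants; the identity
DE(c·x) − DE(x) = ln|c| holds exactly in σ² and anchors several tests.
Channel vectors fill the smallest covering square grid row-major (6×6 for
32 channels), unused cells zero; an electrode-topology layout can be
supplied instead. Band grids stack as feature-map channels into
(s, c, h, w); consecutive windows group into length-8 sequences (the
sequence length with the best reported accuracy in the source experiments;
trailing remainders are dropped, and sequences never span trials).

Binary labels use a strict threshold: rating > 5 is positive, exactly 5 is
negative (the boundary is stated only as "exceeding"; the choice is
configurable). Four-class labels are one-hot encoded where needed.

## Classifier

Wiring per window: conv 4→24 (5×5, padding 2) → ReLU → 2×2 max-pool →
conv 24→128 (2×2, valid) → ReLU → FC 512→96 → ReLU → FC 96→16. The printed
layer table pins FC1's input to 128·2·2 and the recurrent block's
embedding to 16, which is only dimensionally consistent if the FC pair
acts as a per-window embedding head *before* the recurrence; conv padding
and pooling are chosen so the post-conv map is exactly 2×2 on the default
6×6 grid. A bidirectional LSTM (standard gating: c_t = f_t⊙c_{t−1} +
i_t⊙c̃_t, h_t = o_t⊙tanh(c_t); hidden 16 per direction) runs over the 8
embeddings. Attention follows the description of a fully connected layer
mapping each step's hidden state to a scalar: score_t = q·h_t + b with a
learned query row q, scaled by 1/√d_k (d_k = 32, the bidirectional output
width) and softmax-normalized over time; the context vector Σ α_t h_t
feeds a linear class head. A data-dependent query taken from the final
step's output was tried and rejected: it trains worse and cannot locate
informative steps when the last window is uninformative. The general
Q/K/V scaled dot-product primitive is exposed separately and tested
against brute force.

Initialization is uniform fan-in with a fixed seed (determinism is a test
requirement); training is Adam (lr 1e-4, β 0.9/0.999), batch 32,
cross-entropy, a fixed epoch budget with no early stopping, and the
checkpoint with the lowest validation cross-entropy retained — validation
*accuracy* saturates almost immediately on separable synthetic data and
cannot rank checkpoints. The "500 iterations" schedule is read as epochs;
desk-scale experiments use ≤ 200, by which the slowest variant has
converged. Continuous VAD data trains three independent binary classifiers
(one per dimension); four-class data trains a single 4-class model.

Ablations: `no_attention` replaces attention with uniform mean pooling;
`no_bilstm` removes the recurrence and attends directly over the 16-d
embeddings; `neither` mean-pools the embeddings. Everything runs on
`eegemo.nn`, a ~400-line reverse-mode autodiff engine (float64, CPU);
gradients of every primitive are verified against central finite
differences.

## Splits and metrics

The ratio split is contiguous in time — first 60% train, next 20%
validation, last 20% test, no shuffling across boundaries — taking the
stated protocol literally; the alternative trial split uses the first 16
trials for training and the next 8 for test. Metrics: accuracy in percent
per report group with sample standard deviation across groups
(S = √(Σ(x_i − x̄)²/(N−1))); F1 = 2PR/(P+R), binary for two classes and
macro-averaged otherwise (the averaging convention for the reported
four-class F1 is unstated; macro is the common choice and is logged as a
deviation risk); AUC by the rank formulation (ties half), which equals the
trapezoidal ROC area — computed via scikit-learn and cross-checked in
tests against exhaustive pair counting.

## Learning-effectiveness score

Score = 0.3·V + 0.4·A + 0.3·D on the 0–9 scale; arousal carries the
largest weight as the dimension most directly tied to attention and
activation. The four state intervals share printed endpoints, so the
implementation uses half-open intervals with boundaries assigned upward —
[0,3) Ineffective, [3,4) Moderate, [4,6) Good, [6,9] Excellent — making
the mapping total and deterministic. Predicted VAD from binary classifiers
maps positive-class probability linearly to the rating scale (p×9), the
minimal monotone bridge; whether the original demonstration used
regression or thresholded outputs is unknown, so both pathways exist and
neither claims numerical fidelity to it.

## Known limitations

- The ablation comparison does not reproduce the strict ordering
  full > no-attention > no-Bi-LSTM observed on recorded EEG: under this
  generator the class is linearly decodable from sequence-mean DE
  features, so every mean-pooling variant is architecturally sufficient
  and all variants sit at the accuracy ceiling at effect 3 (a ln 3 DE
  shift versus ≈ 0.1 estimator noise). The attention-focus property is
  instead verified directly on burst-structured data, where trained
  attention weights concentrate on informative windows.
- Bessel stop-band attenuation is inherently shallow; applications needing
  strong 50/60 Hz rejection would add a notch, which is out of scope.
- Desk-scale problem sizes (default study: 80 trials × 40 s, 400
  sequences; worked example smaller still) are chosen for single-CPU runs;
  accuracies on such sizes carry a few percentage points of seed-to-seed
  variability.
- No ICA/regression ocular-artifact removal, electrode-position
  interpolation, GPU support, or real-time acquisition.
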