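"""Conv / Bi-LSTM / dynamic-attention classifier over DE feature volumes.

Dataflow for one length-L window sequence of (c, h, w) feature grids:

1. per-window 2-D convolutional encoder: conv1 (c→24, 5×5, padding 2),
   2×2 max pool, conv2 (24→128, 2×2 valid), ReLU throughout — for the
   default 6×6 electrode grid this yields a 128×2×2 map;
2. per-window embedding head: FC1 (128·2·2 → 96) + ReLU, FC2 (96 → 16);
3. Bi-LSTM over the L embeddings (hidden 16 per direction → 32 per step);
4. dynamic attention: a fully connected layer maps each step's recurrent
   output to a scalar relevance score — equivalently a learned query row q
   dotted with each key h_t — the scores are scaled by 1/√d_k and
   softmax-normalized over time, and the context vector is the weighted
   sum of the per-step outputs (values);
5. linear class head on the context.

The printed layer widths (24/128 conv channels, FC1 input 128·2·2, FC2
output 16 feeding the recurrence) uniquely pin the embedding-first wiring;
the convolution padding/pooling plumbing is chosen so conv2's output map is
exactly 2×2 on the default grid.

Ablation variants: ``no_attention`` replaces attention with uniform mean
pooling over time; ``no_bilstm`` drops the recurrence and attends directly
over the per-window embeddings; ``neither`` mean-pools the embeddings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .types import ConfigurationError

ABLATION_VARIANTS = ("full", "no_attention", "no_bilstm", "neither")


@dataclass
class ClassifierConfig:
    """Architecture hyperparameters."""

    in_channels: int = 4          # feature-map channels = number of bands
    grid: tuple[int, int] = (6, 6)
    conv1_out: int = 24
    conv1_kernel: int = 5
    conv2_out: int = 128
    conv2_kernel: int = 2
    fc1_out: int = 96
    embed_dim: int = 16           # FC2 output, the per-window embedding
    lstm_hidden: int = 16
    bidirectional: bool = True
    attention_dim: int | None = None  # d_k; default = recurrent output width
    n_classes: int = 2
    seq_len: int = 8
    ablation: str = "full"

    def __post_init__(self) -> None:
        if self.ablation not in ABLATION_VARIANTS:
            raise ConfigurationError(f"unknown ablation variant {self.ablation!r}; use one of {ABLATION_VARIANTS}")
        if self.seq_len < 1:
            raise ConfigurationError("seq_len must be >= 1")
        if self.attention_dim is not None and self.attention_dim <= 0:
            raise ConfigurationError("attention_dim (d_k) must be positive")
        self.conv_plumbing()  # validates grid vs kernels

    def conv_plumbing(self) -> tuple[int, int, int]:
        """(post-conv2 height, width, flattened FC1 input size)."""
        h, w = self.grid
        pad = self.conv1_kernel // 2
        h1, w1 = h + 2 * pad - self.conv1_kernel + 1, w + 2 * pad - self.conv1_kernel + 1
        hp, wp = h1 // 2, w1 // 2  # 2×2 max pool
        h2, w2 = hp - self.conv2_kernel + 1, wp - self.conv2_kernel + 1
        if h2 < 1 or w2 < 1:
            raise ConfigurationError(
                f"conv2 ({self.conv2_kernel}×{self.conv2_kernel}) infeasible: pooled map is {hp}×{wp} "
                f"for grid {h}×{w}"
            )
        return h2, w2, self.conv2_out * h2 * w2

    @property
    def seq_feature_dim(self) -> int:
        """Width of the per-step vectors the attention pools over."""
        if self.ablation in ("no_bilstm", "neither"):
            return self.embed_dim
        return self.lstm_hidden * (2 if self.bidirectional else 1)

    @property
    def d_k(self) -> int:
        return self.attention_dim if self.attention_dim is not None else self.seq_feature_dim


def attention(Q: Tensor, K: Tensor, V: Tensor, d_k: int) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention: weights = softmax(QKᵀ/√d_k), context = weights·V.

    Q: (B, 1, d_k) queries; K: (B, L, d_k); V: (B, L, D).  Returns
    (context (B, D), weights (B, L)); each weight row sums to 1, so the
    context is a convex combination of the value rows.
    """
    if d_k <= 0:
        raise ConfigurationError("d_k must be positive")
    scores = nn.matmul(Q, K.transpose(0, 2, 1)) * (1.0 / np.sqrt(d_k))  # (B, 1, L)
    weights = nn.softmax(scores, axis=-1)
    context = nn.matmul(weights, V)  # (B, 1, D)
    B, _, D = context.shape
    L = weights.shape[-1]
    return context.reshape(B, D), weights.reshape(B, L)


class ConvBiLSTMAttention:
    """The wired network; use :func:`build_model` to construct one."""

    def __init__(self, cfg: ClassifierConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        h2, w2, fc1_in = cfg.conv_plumbing()
        self.conv1 = nn.Conv2d(cfg.in_channels, cfg.conv1_out, cfg.conv1_kernel, rng, padding=cfg.conv1_kernel // 2)
        self.conv2 = nn.Conv2d(cfg.conv1_out, cfg.conv2_out, cfg.conv2_kernel, rng)
        self.fc1 = nn.Linear(fc1_in, cfg.fc1_out, rng)
        self.fc2 = nn.Linear(cfg.fc1_out, cfg.embed_dim, rng)
        self.bilstm = None
        if cfg.ablation in ("full", "no_attention"):
            self.bilstm = nn.BiLSTM(cfg.embed_dim, cfg.lstm_hidden, rng)
        self.attn_score = None
        if cfg.ablation in ("full", "no_bilstm"):
            # learned query: one FC scalar per time step, scaled by 1/sqrt(d_k)
            self.attn_score = nn.Linear(cfg.seq_feature_dim, 1, rng)
        self.head = nn.Linear(cfg.seq_feature_dim, cfg.n_classes, rng)

    # ---- forward ---------------------------------------------------------
    def encode_windows(self, batch: np.ndarray) -> list[Tensor]:
        """Per-window conv + FC embedding: (B, L, c, h, w) → L tensors (B, E)."""
        B, L = batch.shape[:2]
        x = Tensor(batch.reshape((B * L,) + batch.shape[2:]))
        z = nn.relu(self.conv1(x))
        z = nn.maxpool2d(z, 2)
        z = nn.relu(self.conv2(z))
        z = z.reshape(B * L, -1)
        z = nn.relu(self.fc1(z))
        z = self.fc2(z)
        z = z.reshape(B, L, self.cfg.embed_dim)
        return [z[:, t, :] for t in range(L)]

    def forward(self, batch: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Class scores and attention weights for (B, L, c, h, w) input.

        Returns (logits (B, n_classes), weights (B, L)); weight rows sum
        to 1 (uniform 1/L for the mean-pooling ablations).
        """
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 5:
            raise ValueError(f"batch must be (B, L, c, h, w); got ndim={batch.ndim}")
        if batch.shape[2] != self.cfg.in_channels or batch.shape[3:] != tuple(self.cfg.grid):
            raise ValueError(
                f"batch shape {batch.shape[2:]} does not match configured "
                f"({self.cfg.in_channels}, {self.cfg.grid[0]}, {self.cfg.grid[1]})"
            )
        B, L = batch.shape[:2]
        steps = self.encode_windows(batch)
        if self.bilstm is not None:
            steps = self.bilstm(steps, B)
        H = nn.stack(steps, axis=1)  # (B, L, D)
        if self.attn_score is not None:
            scores = self.attn_score(H).reshape(B, 1, L) * (1.0 / np.sqrt(self.cfg.d_k))
            weights = nn.softmax(scores, axis=-1)
            context = nn.matmul(weights, H).reshape(B, H.shape[-1])
            wdata = weights.data.reshape(B, L)
        else:
            context = H.mean(axis=1)
            wdata = np.full((B, L), 1.0 / L)
        logits = self.head(context)
        return logits, wdata

    def predict(self, batch: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(batch)
        return logits.data.argmax(axis=1)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(batch)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # ---- parameters ------------------------------------------------------
    def params(self) -> list[Tensor]:
        ps = self.conv1.params() + self.conv2.params() + self.fc1.params() + self.fc2.params()
        if self.bilstm is not None:
            ps += self.bilstm.params()
        if self.attn_score is not None:
            ps += self.attn_score.params()
        return ps + self.head.params()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            if p.data.shape != s.shape:
                raise ConfigurationError(f"state shape {s.shape} does not match parameter {p.data.shape}")
            p.data = s.copy()

    # ---- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Architecture JSON + flat parameter arrays in one NPZ."""
        cfg = {**self.cfg.__dict__, "grid": list(self.cfg.grid), "seed": self.seed}
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "ConvBiLSTMAttention":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["config"]))
            seed = meta.pop("seed")
            meta["grid"] = tuple(meta["grid"])
            model = cls(ClassifierConfig(**meta), seed=seed)
            model.set_state([z[f"p{i}"] for i in range(len(model.params()))])
        return model


def build_model(cfg: ClassifierConfig, seed: int = 0) -> ConvBiLSTMAttention:
    """Deterministically initialize the network for ``cfg``."""
    return ConvBiLSTMAttention(cfg, seed=seed)


def ablate(model: ConvBiLSTMAttention, variant: str) -> ConvBiLSTMAttention:
    """A fresh model of the requested ablation variant, same seed/config.

    ``full`` returns an equivalent copy.  The conv/FC encoder shapes are
    shared across variants; the sequence stage and head are re-wired.
    """
    if variant not in ABLATION_VARIANTS:
        raise ConfigurationError(f"unknown ablation variant {variant!r}")
    cfg = replace(model.cfg, ablation=variant)
    return ConvBiLSTMAttention(cfg, seed=model.seed)
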