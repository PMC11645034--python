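"""Minimal reverse-mode autodiff engine and neural layers on NumPy.

Implements exactly the primitives the classifier needs — 2-D convolution,
max pooling, linear maps, an LSTM cell, softmax attention, cross-entropy —
with gradients verified against finite differences in the test suite.
Everything is float64 and CPU-deterministic: the same seed yields the same
parameters and the same training trajectory.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "concat",
    "stack",
    "relu",
    "sigmoid",
    "tanh",
    "softmax",
    "conv2d",
    "maxpool2d",
    "cross_entropy_logits",
    "Linear",
    "Conv2d",
    "LSTMCell",
    "BiLSTM",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ---- autograd driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        # iterative topological sort (post-order)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if not node.requires_grad:
                continue
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- elementwise arithmetic -----------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data), other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division by Tensor not needed")
        return self * (1.0 / other)

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._backward = back
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            g2 = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g2, self.data.shape))

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ---- functional ops ------------------------------------------------------
def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    out = Tensor(a.data @ b.data, parents=(a, b))

    def back(g):
        a._accum(g @ np.swapaxes(b.data, -1, -2))
        b._accum(np.swapaxes(a.data, -1, -2) @ g)

    out._backward = back
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = back
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def back(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    out._backward = back
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x._accum(g * y * (1.0 - y))
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x._accum(g * (1.0 - y * y))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def back(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    out._backward = back
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1: x (N,C,H,W), weight (O,C,kh,kw)."""
    N, C, H, W = x.data.shape
    O, _, kh, kw = weight.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, -1)
    y = (cols @ wmat.T + bias.data).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    out = Tensor(y, parents=(x, weight, bias))

    def back(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
        weight._accum((gmat.T @ cols).reshape(weight.data.shape))
        bias._accum(gmat.sum(axis=0))
        dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    out._backward = back
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k max pooling; trailing rows/cols are cropped."""
    N, C, H, W = x.data.shape
    Ho, Wo = H // k, W // k
    view = x.data[:, :, : Ho * k, : Wo * k].reshape(N, C, Ho, k, Wo, k)
    flat = view.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def back(g):
        dflat = np.zeros((N, C, Ho, Wo, k * k))
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, : Ho * k, : Wo * k] = (
            dflat.reshape(N, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho * k, Wo * k)
        )
        x._accum(dx)

    out._backward = back
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against raw class scores."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    n = len(labels)
    loss = float(np.mean(lse - z[np.arange(n), labels]))
    out = Tensor(loss, parents=(logits,))

    def back(g):
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)

    out._backward = back
    return out


# ---- layers --------------------------------------------------------------
def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_uniform_fan_in(rng, (in_features, out_features), in_features), requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, (out_features,), in_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        return y + self.bias if self.bias is not None else y

    def params(self) -> list[Tensor]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class Conv2d:
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, padding: int = 0):
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_uniform_fan_in(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, (out_ch,), fan_in), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)

    def params(self) -> list[Tensor]:
        return [self.weight, self.bias]


class LSTMCell:
    """Standard gated recurrence.

    c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t,  h_t = o_t ⊙ tanh(c_t), with
    sigmoid-activated forget/input/output gates and tanh candidate.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = Linear(in_features, 4 * hidden, rng)
        self.wh = Linear(hidden, 4 * hidden, rng, bias=False)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = self.wx(x) + self.wh(h)
        H = self.hidden
        i = sigmoid(z[:, 0 * H : 1 * H])
        f = sigmoid(z[:, 1 * H : 2 * H])
        o = sigmoid(z[:, 2 * H : 3 * H])
        g = tanh(z[:, 3 * H : 4 * H])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new

    def run(self, xs: list[Tensor], batch: int) -> list[Tensor]:
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        out = []
        for x in xs:
            h, c = self.step(x, h, c)
            out.append(h)
        return out

    def params(self) -> list[Tensor]:
        return self.wx.params() + self.wh.params()


class BiLSTM:
    """Bidirectional LSTM over a window sequence; outputs are the
    concatenation of the forward and backward hidden states per step."""

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMCell(in_features, hidden, rng)
        self.bwd = LSTMCell(in_features, hidden, rng)

    def __call__(self, xs: list[Tensor], batch: int) -> list[Tensor]:
        hf = self.fwd.run(xs, batch)
        hb = self.bwd.run(xs[::-1], batch)[::-1]
        return [concat([f, b], axis=1) for f, b in zip(hf, hb)]

    def params(self) -> list[Tensor]:
        return self.fwd.params() + self.bwd.params()


class Adam:
    """Adaptive-moment optimizer (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
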