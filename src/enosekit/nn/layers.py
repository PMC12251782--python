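"""Neural building blocks for the concentration models.

All layers operate on time-major feature tensors shaped ``(batch, length,
features)`` and draw their initial weights from an explicit
``numpy.random.Generator`` so a fixed seed reproduces training bit-for-bit
on a single thread.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct as _scipy_dct

from .autograd import Tensor, concatenate, relu, sigmoid, softmax, stack, tanh

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "LSTM",
    "BiLSTM",
    "MLP",
    "DCTAttention",
    "TransformerEncoderLayer",
    "Adam",
    "dct_matrix",
]


class Module:
    """Base class: parameter discovery via attribute traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("shape mismatch in checkpoint")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = _param(rng, (in_dim, out_dim), in_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padded 1-D convolution along the time axis of ``(B, L, C)`` input."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.kernel = kernel
        self.weight = _param(rng, (kernel, in_ch, out_ch), kernel * in_ch)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        k = self.kernel
        left = (k - 1) // 2
        x_pad = _pad_time(x, left, k - 1 - left)
        out = None
        for j in range(k):
            term = x_pad[:, j : j + L, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias


def _pad_time(x: Tensor, left: int, right: int) -> Tensor:
    if left == 0 and right == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    L = x.shape[1]

    def backward(g):
        if x.requires_grad:
            x._accum(g[:, left : left + L, :])

    return Tensor._node(out_data, (x,), backward)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / (var + self.eps).sqrt() * self.gamma + self.beta


class LSTM(Module):
    """Single unidirectional LSTM layer returning the full hidden sequence."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.w_x = _param(rng, (in_dim, 4 * hidden), in_dim)
        self.w_h = _param(rng, (hidden, 4 * hidden), hidden)
        self.bias = Tensor(np.zeros(4 * hidden), requires_grad=True)
        # forget-gate bias of 1: the standard trick to keep early gradients alive
        self.bias.data[hidden : 2 * hidden] = 1.0

    def forward(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor] = []
        for t in range(L):
            z = x[:, t, :] @ self.w_x + h @ self.w_h + self.bias
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * tanh(c)
            outs.append(h)
        return stack(outs, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM layer: forward and time-reversed passes concatenated."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(in_dim, hidden, rng)
        self.bwd = LSTM(in_dim, hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        out_f = self.fwd(x)
        out_b = self.bwd(x[:, ::-1, :])[:, ::-1, :]
        return concatenate([out_f, out_b], axis=-1)


class MLP(Module):
    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
        return x


def dct_matrix(n: int) -> np.ndarray:
    """Orthonormal DCT-II analysis matrix (rows = basis functions)."""
    return _scipy_dct(np.eye(n), type=2, norm="ortho", axis=0)


class DCTAttention(Module):
    """Frequency-domain channel attention.

    Each feature channel is summarised by the summed magnitudes of its first
    ``dct_k`` orthonormal DCT-II coefficients along time; the descriptors pass
    through a squeeze-excite style bottleneck and a sigmoid, and the resulting
    per-channel gates rescale the input.  With all bottleneck weights at zero
    the gates are exactly 0.5.
    """

    def __init__(self, channels: int, seq_len: int, dct_k: int, reduction: int,
                 rng: np.random.Generator):
        if reduction > channels:
            raise ValueError("reduction must not exceed the channel count")
        if dct_k > seq_len:
            raise ValueError("dct_k must not exceed the sequence length")
        self.basis = Tensor(dct_matrix(seq_len)[:dct_k].T)  # (L, k), constant
        self.fc1 = Linear(channels, max(channels // reduction, 1), rng)
        self.fc2 = Linear(max(channels // reduction, 1), channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        coeff = x.swapaxes(1, 2) @ self.basis            # (B, C, k)
        desc = coeff.abs().sum(axis=2)                   # (B, C)
        gate = sigmoid(self.fc2(relu(self.fc1(desc))))   # (B, C)
        return x * gate.reshape(B, 1, C)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)                                 # (B, L, 3D)
        q = qkv[:, :, :D].reshape(B, L, H, dh).swapaxes(1, 2)
        k = qkv[:, :, D : 2 * D].reshape(B, L, H, dh).swapaxes(1, 2)
        v = qkv[:, :, 2 * D :].reshape(B, L, H, dh).swapaxes(1, 2)
        scores = (q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder block (attention + position-wise FFN)."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.norm2 = LayerNorm(d_model)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(x + self.attn(x))
        return self.norm2(h + self.ff2(relu(self.ff1(h))))


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
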