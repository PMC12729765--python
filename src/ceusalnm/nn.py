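"""Neural-network building blocks on top of :mod:`ceusalnm.autodiff`.

Layers follow pre-LayerNorm transformer conventions.  Every module takes an
explicit ``numpy.random.Generator`` for initialization so that whole models
are reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concatenate, softmax, stack


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for name, array in state.items():
            if name not in own:
                raise KeyError(f"unknown parameter {name!r}")
            if own[name].data.shape != array.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: "
                    f"{own[name].data.shape} vs {array.shape}"
                )
            own[name].data = np.asarray(array, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True,
                 scale: float | None = None):
        if scale is None:
            scale = 1.0 / math.sqrt(d_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, scale, size=(n, d)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids)]


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Bidirectional self-attention over (B, L, d) with an optional key mask.

    ``key_mask`` (B, L) marks valid positions; masked keys receive -1e9 before
    the softmax so padding can never influence other tokens.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("embed dim must be divisible by n_heads")
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.qkv = Linear(d, 3 * d, rng)
        self.out = Linear(d, d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        B, L, d = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, L, 3d)
        qkv = qkv.reshape(B, L, 3, h, dh).swapaxes(1, 3)  # (B, h, 3, L, dh)
        q, k, v = qkv[:, :, 0], qkv[:, :, 1], qkv[:, :, 2]
        scores = (q @ k.T) * (1.0 / math.sqrt(dh))  # (B, h, L, L)
        if key_mask is not None:
            bias = np.where(key_mask[:, None, None, :], 0.0, -1e9)
            scores = scores + Tensor(bias)
        attn = softmax(scores, axis=-1)
        ctx = attn @ v  # (B, h, L, dh)
        ctx = ctx.swapaxes(1, 2).reshape(B, L, d)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-LN block: x + MHSA(LN(x)); x + MLP(LN(x)) with a 4x GELU-free MLP.

    ReLU is used in the feed-forward (matching the adapter's activation and
    keeping the op set small).
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, mlp_ratio: int = 4):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, mlp_ratio * d, rng)
        self.fc2 = Linear(mlp_ratio * d, d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), key_mask)
        x = x + self.fc2(self.fc1(self.ln2(x)).relu())
        return x


class LSTM(Module):
    """Single-layer unidirectional LSTM; returns the final hidden state."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        s_in = 1.0 / math.sqrt(d_in)
        s_h = 1.0 / math.sqrt(d_hidden)
        self.w_x = Parameter(rng.normal(0.0, s_in, size=(d_in, 4 * d_hidden)))
        self.w_h = Parameter(rng.normal(0.0, s_h, size=(d_hidden, 4 * d_hidden)))
        bias = np.zeros(4 * d_hidden)
        bias[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias at 1
        self.bias = Parameter(bias)

    def __call__(self, xs: Tensor) -> Tensor:
        """xs: (B, T, d_in) -> final hidden state (B, d_hidden)."""
        B, T, _ = xs.shape
        dh = self.d_hidden
        h = Tensor(np.zeros((B, dh)))
        c = Tensor(np.zeros((B, dh)))
        for t in range(T):
            gates = xs[:, t] @ self.w_x + h @ self.w_h + self.bias
            i = gates[:, :dh].sigmoid()
            f = gates[:, dh : 2 * dh].sigmoid()
            g = gates[:, 2 * dh : 3 * dh].tanh()
            o = gates[:, 3 * dh :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


__all__ = [
    "Parameter", "Module", "Linear", "Embedding", "LayerNorm",
    "MultiHeadSelfAttention", "TransformerEncoderLayer", "LSTM", "AdamW",
    "Tensor", "concatenate", "softmax", "stack",
]
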