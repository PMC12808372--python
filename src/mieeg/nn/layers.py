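"""Neural-network modules built on the autograd engine.

Initialization follows fan-in uniform schemes (U(-1/sqrt(fan_in),
1/sqrt(fan_in))), drawn from an explicit ``numpy.random.Generator`` so that
model construction is fully reproducible from a seed. Dropout draws masks
from a shared, reseedable generator owned by the enclosing model, keeping
whole training runs deterministic.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "Dropout",
    "Activation",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "LSTM",
    "RngBox",
    "make_activation",
]


class RngBox:
    """Mutable holder for a random generator, shared by stochastic layers."""

    def __init__(self, seed: int = 0):
        self.gen = np.random.default_rng(np.random.SeedSequence(seed))

    def reseed(self, seed: int) -> None:
        self.gen = np.random.default_rng(np.random.SeedSequence(seed))


class Module:
    """Minimal module base: parameter registry, train/eval mode, recursion."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _members(self):
        return vars(self).items()

    def named_parameters(self, prefix: str = ""):
        for name, value in self._members():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=path + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, value in self._members():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self, trainable_only: bool = True) -> int:
        return sum(
            p.size
            for p in self.parameters()
            if p.requires_grad or not trainable_only
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = sorted(set(own) ^ set(state))
            raise ValueError(f"state_dict mismatch on parameters: {missing}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for '{name}': {p.data.shape} vs "
                    f"{state[name].shape}"
                )
            p.data = state[name].copy()


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._n = len(tuple(modules))

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __len__(self):
        return self._n

    def __getitem__(self, i):
        return getattr(self, f"m{i}")


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _uniform(rng, fan_in: int, shape) -> np.ndarray:
    k = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-k, k, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(
            _uniform(rng, in_features, (in_features, out_features)),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_uniform(rng, in_features, (out_features,)), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out if self.bias is None else out + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator,
                 pad: tuple[int, int] = (0, 0)):
        super().__init__()
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.weight = Tensor(
            _uniform(rng, fan_in, (out_channels, in_channels, kh, kw)),
            requires_grad=True,
        )
        self.bias = Tensor(_uniform(rng, fan_in, (out_channels,)), requires_grad=True)
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, pad=self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (B, H, W) with running stats."""

    def __init__(self, n_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            m, v = mean.data.reshape(-1), var.data.reshape(-1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * m
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * v
            )
            norm = centered * ((var + self.eps) ** -0.5)
        else:
            shape = (1, -1, 1, 1)
            norm = (x - self.running_mean.reshape(shape)) * (
                1.0 / np.sqrt(self.running_var + self.eps).reshape(shape)
            )
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return norm * g + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(eps=self.eps) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng_box: RngBox):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng_box = rng_box

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng_box.gen.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Activation(Module):
    def __init__(self, kind: str):
        super().__init__()
        self.kind = kind.lower()
        if self.kind not in {"relu", "elu", "tanh", "gelu"}:
            raise ValueError(f"unknown activation '{kind}'")

    def forward(self, x: Tensor) -> Tensor:
        return getattr(x, self.kind)()


def make_activation(kind: str) -> Activation:
    return Activation(kind)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` heads."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, d = self.n_heads, self.head_dim
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, h, d).transpose(2, 0, 3, 1, 4)  # (3,B,h,T,d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (B, h, T, d)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: LN(x + MHA(x)), then LN(x + FFN(x))."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator, activation: str = "gelu"):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.act = Activation(activation)
        self.norm2 = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        x = self.norm2(x + self.ff2(self.act(self.ff1(x))))
        return x


class LSTM(Module):
    """Single-layer unidirectional LSTM unrolled over (B, T, D) input."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, reverse: bool = False):
        super().__init__()
        self.hidden_size = hidden_size
        self.reverse = reverse
        self.w_ih = Tensor(
            _uniform(rng, hidden_size, (input_size, 4 * hidden_size)),
            requires_grad=True,
        )
        self.w_hh = Tensor(
            _uniform(rng, hidden_size, (hidden_size, 4 * hidden_size)),
            requires_grad=True,
        )
        self.bias = Tensor(
            _uniform(rng, hidden_size, (4 * hidden_size,)), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden_size
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        # precompute the input projection for all steps at once
        xin = x @ self.w_ih + self.bias  # (B, T, 4H)
        outputs: list[Tensor | None] = [None] * T
        for t in order:
            gates = xin[:, t, :] + h @ self.w_hh
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h.reshape(B, 1, H)
        return concat(outputs, axis=1)  # (B, T, H)
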