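"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

The engine provides exactly the operator set the hybrid decoder needs:
broadcasting arithmetic, matmul, shape ops, reductions, the nonlinearities
(ReLU / ELU / Tanh / sigmoid / GELU), softmax, layer normalization, 2-D
convolution and temporal pooling. Tensors form a dynamic graph; calling
:meth:`Tensor.backward` walks it once in reverse topological order and
accumulates gradients into every tensor with ``requires_grad``.

Design constraints: float64 throughout (gradient checks to 1e-6), iterative
topological sort (graphs from unrolled LSTMs exceed recursion limits), and no
operator mutates its inputs, so frozen parameters stay bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._children: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _node(data, children, backward) -> "Tensor":
        out = Tensor(data)
        if any(c.requires_grad for c in children):
            out.requires_grad = True
            out._children = tuple(children)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._children:
                if child.requires_grad and id(child) not in seen:
                    stack.append((child, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._node(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._node(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / (2.0 * out_data))

        return self._node(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._node(np.where(mask, self.data, 0.0), (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        expx = np.exp(np.minimum(self.data, 0.0))

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, alpha * expx))

        out_data = np.where(pos, self.data, alpha * (expx - 1.0))
        return self._node(out_data, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        from scipy.special import erf

        cdf = 0.5 * (1.0 + erf(self.data / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * self.data**2) / math.sqrt(2.0 * math.pi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (cdf + self.data * pdf))

        return self._node(self.data * cdf, (self,), backward)

    # -- reductions & shape ops -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._node(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            denom = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        parts = key if isinstance(key, tuple) else (key,)
        advanced = any(isinstance(k, (np.ndarray, list)) for k in parts)

        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                if advanced:  # indices may repeat -> scatter-add
                    np.add.at(self.grad, key, g)
                else:  # basic slicing never aliases
                    self.grad[key] += g

        return self._node(self.data[key], (self,), backward)

    # -- fused numerical ops ----------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._node(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return self._node(out_data, (self,), backward)

    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean / unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv
        n = self.shape[-1]

        def backward(g):
            if self.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gx = (g * out_data).mean(axis=-1, keepdims=True)
                self._accum(inv * (g - gm - out_data * gx))

        return self._node(out_data, (self,), backward)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               pad: tuple[int, int] = (0, 0)):
        """2-D cross-correlation, stride 1, zero padding ``(pad_h, pad_w)``.

        ``self``: (B, Cin, H, W); ``weight``: (Cout, Cin, kh, kw). The
        kernel-tap loop keeps peak memory at one (B, C, H, W) buffer, which
        matters for long temporal kernels on EEG epochs.
        """
        x = self.data
        w = weight.data
        ph, pw = pad
        B, Ci, H, W = x.shape
        Co, Ci2, kh, kw = w.shape
        if Ci != Ci2:
            raise ValueError("conv2d channel mismatch")
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
        Ho = H + 2 * ph - kh + 1
        Wo = W + 2 * pw - kw + 1
        out_data = np.zeros((B, Co, Ho, Wo))
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + Ho, j : j + Wo]
                out_data += np.einsum(
                    "bchw,oc->bohw", patch, w[:, :, i, j], optimize=True
                )
        if bias is not None:
            out_data += bias.data[None, :, None, None]

        children = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            if weight.requires_grad:
                gw = np.zeros_like(w)
                for i in range(kh):
                    for j in range(kw):
                        patch = xp[:, :, i : i + Ho, j : j + Wo]
                        gw[:, :, i, j] = np.einsum(
                            "bchw,bohw->oc", patch, g, optimize=True
                        )
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + Ho, j : j + Wo] += np.einsum(
                            "bohw,oc->bchw", g, w[:, :, i, j], optimize=True
                        )
                self._accum(
                    gxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gxp
                )

        return self._node(out_data, children, backward)

    def max_pool_time(self, stride: int):
        """Non-overlapping max pooling over axis 2 of a (B, C, T, W) tensor."""
        B, C, T, W = self.shape
        To = T // stride
        crop = self.data[:, :, : To * stride, :]
        win = crop.reshape(B, C, To, stride, W)
        arg = win.argmax(axis=3)
        out_data = np.take_along_axis(win, arg[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

        def backward(g):
            if self.requires_grad:
                full = np.zeros((B, C, To, stride, W))
                np.put_along_axis(full, arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
                gx = np.zeros_like(self.data)
                gx[:, :, : To * stride, :] = full.reshape(B, C, To * stride, W)
                self._accum(gx)

        return self._node(out_data, (self,), backward)

    def avg_pool_time(self, stride: int):
        """Non-overlapping average pooling over axis 2 of (B, C, T, W)."""
        B, C, T, W = self.shape
        To = T // stride
        crop = self.data[:, :, : To * stride, :]
        out_data = crop.reshape(B, C, To, stride, W).mean(axis=3)

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                gx[:, :, : To * stride, :] = np.repeat(
                    g / stride, stride, axis=2
                )
                self._accum(gx)

        return self._node(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis with gradient splitting."""

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._node(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
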