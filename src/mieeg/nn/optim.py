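"""Optimizers and loss functions for the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "cross_entropy"]


class Adam:
    """Adam with bias correction; parameters with ``requires_grad=False``
    are excluded entirely, so frozen tensors stay bit-identical."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between logits (B, K) and integer labels (B,)."""
    labels = np.asarray(labels, dtype=np.int64)
    log_p = logits.log_softmax(axis=-1)
    picked = log_p[np.arange(len(labels)), labels]
    return -picked.mean()
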