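"""AdamW with decoupled weight decay and a cosine-annealing schedule."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "cosine_lr"]


def cosine_lr(base_lr: float, epoch: int, max_epochs: int,
              min_lr: float = 0.0) -> float:
    """Cosine annealing from base_lr at epoch 0 down to min_lr at max_epochs."""
    if max_epochs <= 1:
        return base_lr
    t = min(epoch, max_epochs - 1) / (max_epochs - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + np.cos(np.pi * t))


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 3.28e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.028):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            # decoupled weight decay: shrink the parameter directly
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
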