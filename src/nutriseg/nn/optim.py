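"""Adam optimizer and the per-epoch exponential learning-rate schedule
(lr_e = lr0 * decay^e) used by both training loops."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "ExponentialDecay"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ExponentialDecay:
    """lr at epoch e is lr0 * rate**e; call step() once per epoch."""

    def __init__(self, optimizer: Adam, rate: float = 0.99):
        self.optimizer = optimizer
        self.rate = float(rate)
        self.lr0 = optimizer.lr
        self.epoch = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.rate ** epoch

    def step(self):
        self.epoch += 1
        self.optimizer.lr = self.lr_at(self.epoch)
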