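"""Adam optimizer and the piecewise (step-decay) learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "piecewise_lr"]


class Adam:
    """Adam with decoupled-from-nothing classic L2: wd * theta added to grads."""

    def __init__(self, params, lr: float = 0.01, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def piecewise_lr(initial_lr: float, epoch: int, drop_period: int, drop_factor: float) -> float:
    """Step schedule: lr = initial * factor ** floor((epoch - 1) / period).

    ``epoch`` is 1-based; e.g. initial 0.01, period 10, factor 0.5 gives
    0.01 for epochs 1-10, 0.005 for 11-20, 0.0025 for 21-30.
    """
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return initial_lr * drop_factor ** ((epoch - 1) // drop_period)
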