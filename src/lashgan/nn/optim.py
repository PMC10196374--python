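"""Adam optimizer for :class:`~lashgan.nn.layers.Parameter` lists."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with the momentum pair conventionally used for adversarial training.

    beta1 = 0.5 damps the oscillation between generator and discriminator
    updates; the remaining defaults are the standard Adam values.
    """

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
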