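"""Adam optimizer over a flat list of (params, grads) dictionaries."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction (defaults: lr 1e-4, beta1 0.9, beta2 0.999)."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for i, layer in enumerate(self.layers):
            for key, p in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                sk = (i, key)
                m = self._m.setdefault(sk, np.zeros_like(p))
                v = self._v.setdefault(sk, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
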