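"""Stochastic gradient descent with Nesterov momentum and weight decay.

Matches the common deep-learning convention: with momentum m, weight decay
wd and learning rate lr,

    g   <- grad + wd * p
    buf <- m * buf + g
    p   <- p - lr * (g + m * buf)        (Nesterov)
    p   <- p - lr * buf                  (plain momentum)
"""

from __future__ import annotations

import numpy as np

from .layers import Module


class SGD:
    def __init__(self, model: Module, lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4, nesterov: bool = True) -> None:
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov
        self._buf: dict[str, np.ndarray] = {}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for path, mod, name in self.model.named_parameters():
            p = mod.params[name]
            g = mod.grads.get(name)
            if g is None:
                continue
            g = g.astype(np.float32) + self.weight_decay * p
            buf = self._buf.get(path)
            buf = g if buf is None else self.momentum * buf + g
            self._buf[path] = buf
            d = g + self.momentum * buf if self.nesterov else buf
            mod.params[name] = p - np.float32(lr) * d
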