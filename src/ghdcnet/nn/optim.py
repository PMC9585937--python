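"""Adam optimizer (adaptive moment estimation) with classic L2 weight decay
added to the gradient, matching the common framework default.

All parameters are repacked into one flat buffer at construction (their
``data`` arrays become views into it), so a step is a handful of vectorized
array operations instead of per-parameter python loops."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        n = sum(p.data.size for p in self.params)
        dtype = self.params[0].data.dtype if self.params else np.float32
        self._flat = np.empty(n, dtype=dtype)
        self._slices = []
        offset = 0
        for p in self.params:
            sl = slice(offset, offset + p.data.size)
            self._flat[sl] = p.data.ravel()
            p.data = self._flat[sl].reshape(p.data.shape)  # parameter views the buffer
            self._slices.append(sl)
            offset += p.data.size
        self._m = np.zeros(n, dtype=dtype)
        self._v = np.zeros(n, dtype=dtype)
        self._g = np.empty(n, dtype=dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        g = self._g
        for p, sl in zip(self.params, self._slices):
            if p.grad is None:
                g[sl] = 0.0
            else:
                g[sl] = p.grad.ravel()
        if self.weight_decay:
            g += self.weight_decay * self._flat
        self._m *= b1
        self._m += (1.0 - b1) * g
        self._v *= b2
        self._v += (1.0 - b2) * g * g
        denom = np.sqrt(self._v / (1.0 - b2**self.t))
        denom += self.eps
        self._flat -= (self.lr / (1.0 - b1**self.t)) * self._m / denom
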