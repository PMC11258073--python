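"""Nadam: Adam with Nesterov momentum (Dozat 2016 formulation)."""

from __future__ import annotations

import numpy as np


class Nadam:
    """Updates parameter arrays in place from their gradient buffers.

    ``l2`` adds weight decay ``l2 * w`` to the gradient of every parameter
    whose name is listed in ``decay_names`` (convolution kernels only by
    convention; biases and normalisation affines are not decayed).
    """

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, l2: float = 0.0,
                 decay_names: tuple = ("w",)):
        # params: list of (name, value, grad) triples; values updated in place
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.l2 = float(l2)
        self.decay_names = set(decay_names)
        self.t = 0
        self._m = [np.zeros_like(v) for _, v, _ in self.params]
        self._v = [np.zeros_like(v) for _, v, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (name, value, grad), m, v in zip(self.params, self._m, self._v):
            g = grad
            if self.l2 > 0 and name in self.decay_names:
                g = g + self.l2 * value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            m_hat = m / bc1
            v_hat = v / bc2
            # Nesterov look-ahead on the first moment
            update = (b1 * m_hat + (1 - b1) * g / bc1) / (np.sqrt(v_hat) + self.eps)
            value -= self.lr * update

    def l2_penalty(self) -> float:
        """Current 0.5 * l2 * ||w||^2 term (for loss reporting)."""
        if self.l2 == 0:
            return 0.0
        return 0.5 * self.l2 * float(sum(
            np.square(v).sum() for n, v, _ in self.params if n in self.decay_names))
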