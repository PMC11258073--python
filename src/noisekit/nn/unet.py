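"""A 3D U-Net assembled from the numpy layers.

Standard encoder/decoder with skip connections: each resolution level is two
3x3x3 convolutions with instance normalisation and ReLU; 2x max-pooling down,
nearest-neighbour 2x upsampling plus channel concatenation up, and a final
1x1x1 convolution to class logits.  Dropout is placed before the last and
second-to-last convolutions.  Depth (resolution levels) and base width are
configurable; input spatial dims must be divisible by 2^(levels-1).
"""

from __future__ import annotations

import numpy as np

from .layers import Conv3d, Dropout, InstanceNorm3d, MaxPool2, ReLU, Upsample2


class _ConvBlock:
    """Conv-IN-ReLU twice, optionally with dropout before the second conv."""

    def __init__(self, c_in, c_out, rng, dropout_rate=0.0, dropout_rng=None):
        self.layers = [Conv3d(c_in, c_out, 3, rng), InstanceNorm3d(c_out), ReLU()]
        if dropout_rate > 0:
            self.layers.append(Dropout(dropout_rate, dropout_rng))
        self.layers += [Conv3d(c_out, c_out, 3, rng), InstanceNorm3d(c_out), ReLU()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for j, layer in enumerate(self.layers):
            for name, v, g in layer.params():
                out.append((f"{j}.{name}", v, g))
        return out


class UNet3D:
    def __init__(self, in_channels: int = 1, n_classes: int = 4,
                 levels: int = 2, base_width: int = 8,
                 dropout_rate: float = 0.5, seed: int = 0):
        if levels < 1:
            raise ValueError("levels must be >= 1")
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        self.levels = levels
        self.base_width = base_width
        self.n_classes = n_classes
        self.in_channels = in_channels
        self.dropout_rate = dropout_rate

        widths = [base_width * 2 ** i for i in range(levels)]
        self.enc = []
        c = in_channels
        for i in range(levels - 1):
            self.enc.append(_ConvBlock(c, widths[i], rng))
            c = widths[i]
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.bottom = _ConvBlock(c, widths[-1], rng)
        self.ups = [Upsample2() for _ in range(levels - 1)]
        self.dec = []
        for i in reversed(range(levels - 1)):
            # level 0 hosts the second-to-last convolution -> dropout there
            rate = dropout_rate if i == 0 else 0.0
            self.dec.append(_ConvBlock(widths[i] + widths[i + 1], widths[i], rng,
                                       dropout_rate=rate,
                                       dropout_rng=self.dropout_rng))
        self.final_dropout = Dropout(dropout_rate, self.dropout_rng)
        self.final = Conv3d(widths[0], n_classes, 1, rng)
        self._skip_channels = widths[:-1]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, D, H, W) float input -> (N, n_classes, D, H, W) logits."""
        div = 2 ** (self.levels - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {div}")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottom.forward(x, train)
        for j, block in enumerate(self.dec):
            i = self.levels - 2 - j
            x = self.ups[j].forward(x, train)
            x = np.concatenate([skips[i], x], axis=1)
            x = block.forward(x, train)
        x = self.final_dropout.forward(x, train)
        return self.final.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.final.backward(dlogits)
        dy = self.final_dropout.backward(dy)
        dskips = [None] * (self.levels - 1)
        for j in reversed(range(len(self.dec))):
            i = self.levels - 2 - j
            dy = self.dec[j].backward(dy)
            c = self._skip_channels[i]
            dskips[i] = dy[:, :c]
            dy = self.ups[j].backward(dy[:, c:])
        dy = self.bottom.backward(dy)
        for i in reversed(range(self.levels - 1)):
            dy = self.pools[i].backward(dy)
            dy = self.enc[i].backward(dy + dskips[i])

    # -- parameters and state ----------------------------------------------

    def params(self):
        out = []
        for i, block in enumerate(self.enc):
            out += [(f"enc{i}.{n}", v, g) for n, v, g in block.params()]
        out += [(f"bottom.{n}", v, g) for n, v, g in self.bottom.params()]
        for j, block in enumerate(self.dec):
            out += [(f"dec{j}.{n}", v, g) for n, v, g in block.params()]
        out += [(f"final.{n}", v, g) for n, v, g in self.final.params()]
        return out

    def optimizer_params(self):
        """(base name, value, grad) with conv kernels named 'w' for L2 decay."""
        return [(name.rsplit(".", 1)[-1], v, g) for name, v, g in self.params()]

    def state_dict(self) -> dict:
        return {name: v.copy() for name, v, _ in self.params()}

    def load_state_dict(self, state: dict) -> None:
        for name, v, _ in self.params():
            v[...] = state[name]

    @property
    def config(self) -> dict:
        return {"in_channels": self.in_channels, "n_classes": self.n_classes,
                "levels": self.levels, "base_width": self.base_width,
                "dropout_rate": self.dropout_rate}
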