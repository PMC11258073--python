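"""Softmax cross-entropy with an ignore label.

Voxels carrying the ignore label contribute nothing to the loss and receive
an exactly zero gradient, so ill-defined annotation regions (segmentation
edges, distal artery voxels) never influence training.
"""

from __future__ import annotations

import numpy as np

IGNORE_LABEL = 255


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, ignore_label: int = IGNORE_LABEL
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over non-ignored voxels, and the logits gradient.

    ``logits``: (N, C, D, H, W); ``targets``: (N, D, H, W) integer labels.
    Returns ``(loss, dlogits)``; with zero valid voxels the loss is 0 with a
    zero gradient.
    """
    n, c = logits.shape[:2]
    p = softmax(logits, axis=1)
    valid = targets != ignore_label
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    t = np.where(valid, targets, 0)
    onehot = np.moveaxis(np.eye(c, dtype=logits.dtype)[t], -1, 1)
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(onehot * logp).sum(axis=1)[valid].mean())
    grad = (p - onehot) / n_valid
    grad *= valid[:, None].astype(logits.dtype)
    return loss, grad.astype(logits.dtype)


def voxel_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, ignore_label: int = IGNORE_LABEL
) -> np.ndarray:
    """Per-voxel cross-entropy map, 0 at ignored voxels (for hard mining)."""
    p = softmax(logits, axis=1)
    valid = targets != ignore_label
    t = np.where(valid, targets, 0)
    picked = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    return np.where(valid, -np.log(np.clip(picked, 1e-12, None)), 0.0)
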