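"""Convolutional and per-pixel fully connected primitives.

All functions operate on batched feature grids of shape (B, h, w, c) and come
in forward/backward pairs so the training loop can backpropagate through the
whole network without an external autodiff framework. Caches returned by the
forward functions hold exactly what the matching backward needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv3x3_forward", "conv3x3_backward",
    "fc_forward", "fc_backward",
    "softmax",
]


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 convolution with zero padding (same size) and tanh non-linearity.

    x : (B, h, w, cin); w : (3, 3, cin, cout); b : (cout,).
    Returns (y, cache) with y = tanh(conv(x) + b).
    """
    B, h, wd, cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    a = np.zeros((B, h, wd, w.shape[3]), dtype=x.dtype)
    for dy in range(3):
        for dx in range(3):
            a += xp[:, dy:dy + h, dx:dx + wd, :] @ w[dy, dx]
    y = np.tanh(a + b)
    return y, {"xp": xp, "y": y, "w": w}


def conv3x3_backward(dy: np.ndarray, cache: dict):
    """Gradients of :func:`conv3x3_forward`; returns (dx, dw, db)."""
    xp, y, w = cache["xp"], cache["y"], cache["w"]
    B, hp, wp, cin = xp.shape
    h, wd = hp - 2, wp - 2
    da = dy * (1.0 - y * y)
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for dyi in range(3):
        for dxi in range(3):
            sl = xp[:, dyi:dyi + h, dxi:dxi + wd, :]
            dw[dyi, dxi] = np.tensordot(sl, da, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, dyi:dyi + h, dxi:dxi + wd, :] += da @ w[dyi, dxi].T
    db = da.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dw, db


def fc_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, relu: bool):
    """Per-pixel dense layer, optionally followed by ReLU."""
    a = x @ w + b
    y = np.maximum(a, 0) if relu else a
    return y, {"x": x, "y": y, "w": w, "relu": relu}


def fc_backward(dy: np.ndarray, cache: dict):
    x, y, w = cache["x"], cache["y"], cache["w"]
    da = dy * (y > 0) if cache["relu"] else dy
    cout = w.shape[1]
    da2 = da.reshape(-1, cout)
    dw = x.reshape(-1, w.shape[0]).T @ da2
    db = da2.sum(axis=0)
    dx = da @ w.T
    return dx, dw, db


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(dp: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. softmax inputs given gradient w.r.t. probabilities."""
    return p * (dp - (dp * p).sum(axis=-1, keepdims=True))
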