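"""The full segmentation network: conv - MDLSTM - conv - MDLSTM - FC - softmax.

Architecture (channels in -> out), applied to arbitrary image sizes h x w:

    3x3 convolution, tanh          1   -> 1
    MDLSTM layer (4 blocks, u)     1   -> 4u
    3x3 convolution, tanh          4u  -> 1
    MDLSTM layer (4 blocks, u)     1   -> 4u
    fully connected, ReLU          4u  -> hidden
    fully connected                hidden -> 2
    softmax                        2   -> 2   (background, cone)

The convolutions between MDLSTM layers aggregate the 4u directional features
into a single channel, which cuts the per-pixel cost of the next MDLSTM block
from 5*u*4u + 10u^2 + 6u multiplications down to 5*u + 10u^2 + 6u; with
u = 32 that is 10592 instead of 30912 per block application.

Because the recurrence carries state across the whole grid, the probability
assigned to any pixel depends on every other pixel -- global context, the
property that lets the model tell a true cone from cone-looking background
in low-quality pathological images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .layers import (conv3x3_backward, conv3x3_forward, fc_backward,
                     fc_forward, softmax, softmax_backward)
from .mdlstm import (BlockWeights, _rot_batch, _scan_backward, _scan_forward,
                     count_block_multiplications)

__all__ = [
    "NetworkParams",
    "init_params",
    "forward",
    "forward_batch",
    "backward_batch",
    "count_network_multiplications",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkParams:
    """All learnable parameters, with stable names for serialisation."""

    conv1_w: np.ndarray            # (3, 3, 1, 1)
    conv1_b: np.ndarray            # (1,)
    mdlstm1: list[BlockWeights]    # 4 blocks, u units, k=1
    conv2_w: np.ndarray            # (3, 3, 4u, 1)
    conv2_b: np.ndarray            # (1,)
    mdlstm2: list[BlockWeights]    # 4 blocks, u units, k=1
    fc1_w: np.ndarray              # (4u, hidden)
    fc1_b: np.ndarray              # (hidden,)
    fc2_w: np.ndarray              # (hidden, 2)
    fc2_b: np.ndarray              # (2,)

    @property
    def units(self) -> int:
        return self.mdlstm1[0].units

    @property
    def hidden(self) -> int:
        return self.fc1_w.shape[1]

    def arrays(self):
        """Yield (name, array) pairs over every parameter, in a fixed order."""
        yield "conv1/w", self.conv1_w
        yield "conv1/b", self.conv1_b
        for li, blocks in (("mdlstm1", self.mdlstm1), ("mdlstm2", self.mdlstm2)):
            for d, blk in enumerate(blocks):
                for arr in ("wx", "wh_up", "wh_left", "bias"):
                    yield f"{li}/d{d}/{arr}", getattr(blk, arr)
        yield "conv2/w", self.conv2_w
        yield "conv2/b", self.conv2_b
        yield "fc_hidden/w", self.fc1_w
        yield "fc_hidden/b", self.fc1_b
        yield "fc_out/w", self.fc2_w
        yield "fc_out/b", self.fc2_b

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            conv1_w=self.conv1_w.copy(), conv1_b=self.conv1_b.copy(),
            mdlstm1=[BlockWeights(b.wx.copy(), b.wh_up.copy(),
                                  b.wh_left.copy(), b.bias.copy())
                     for b in self.mdlstm1],
            conv2_w=self.conv2_w.copy(), conv2_b=self.conv2_b.copy(),
            mdlstm2=[BlockWeights(b.wx.copy(), b.wh_up.copy(),
                                  b.wh_left.copy(), b.bias.copy())
                     for b in self.mdlstm2],
            fc1_w=self.fc1_w.copy(), fc1_b=self.fc1_b.copy(),
            fc2_w=self.fc2_w.copy(), fc2_b=self.fc2_b.copy(),
        )


def init_params(seed: int, units: int = 32, hidden: int = 64,
                mdlstm_sd: float = 0.25, conv_limit: float = 0.1,
                dtype=np.float32) -> NetworkParams:
    """Reproducible initialisation.

    MDLSTM weights ~ Normal(0, sd=``mdlstm_sd``); convolutional filters and
    (by the same rule) fully connected weights ~ Uniform(-``conv_limit``,
    ``conv_limit``); every bias starts at zero. Small recurrent weights are
    essential: large ones make the 2D scan's gradients explode.
    """
    rng = np.random.default_rng(seed)

    def conv_init(*shape):
        return rng.uniform(-conv_limit, conv_limit, shape).astype(dtype)

    return NetworkParams(
        conv1_w=conv_init(3, 3, 1, 1),
        conv1_b=np.zeros(1, dtype=dtype),
        mdlstm1=[BlockWeights.random(units, 1, rng, sd=mdlstm_sd, dtype=dtype)
                 for _ in range(4)],
        conv2_w=conv_init(3, 3, 4 * units, 1),
        conv2_b=np.zeros(1, dtype=dtype),
        mdlstm2=[BlockWeights.random(units, 1, rng, sd=mdlstm_sd, dtype=dtype)
                 for _ in range(4)],
        fc1_w=conv_init(4 * units, hidden),
        fc1_b=np.zeros(hidden, dtype=dtype),
        fc2_w=conv_init(hidden, 2),
        fc2_b=np.zeros(2, dtype=dtype),
    )


def _layer_forward(x: np.ndarray, blocks: list[BlockWeights],
                   want_cache: bool):
    """Four directional scans, concatenated along channels (batched)."""
    outs, caches = [], []
    for d, blk in enumerate(blocks):
        xr = _rot_batch(x, d)
        H, cache = _scan_forward(xr, blk, want_cache=want_cache)
        outs.append(_rot_batch(H, -d))
        caches.append(cache)
    return np.concatenate(outs, axis=-1), caches


def _layer_backward(dy: np.ndarray, caches, blocks: list[BlockWeights]):
    u = blocks[0].units
    dx = None
    grads = []
    for d, (blk, cache) in enumerate(zip(blocks, caches)):
        dH = _rot_batch(dy[..., d * u:(d + 1) * u], d)
        dxr, g = _scan_backward(dH, cache, blk)
        dxd = _rot_batch(dxr, -d)
        dx = dxd if dx is None else dx + dxd
        grads.append(g)
    return dx, grads


def forward_batch(x: np.ndarray, params: NetworkParams,
                  want_cache: bool = False):
    """Forward pass on a batch (B, h, w, 1) -> probabilities (B, h, w, 2)."""
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in network input")
    c1, cc1 = conv3x3_forward(x, params.conv1_w, params.conv1_b)
    m1, cm1 = _layer_forward(c1, params.mdlstm1, want_cache)
    c2, cc2 = conv3x3_forward(m1, params.conv2_w, params.conv2_b)
    m2, cm2 = _layer_forward(c2, params.mdlstm2, want_cache)
    z1, cf1 = fc_forward(m2, params.fc1_w, params.fc1_b, relu=True)
    z2, cf2 = fc_forward(z1, params.fc2_w, params.fc2_b, relu=False)
    probs = softmax(z2)
    if not want_cache:
        return probs, None
    return probs, {"cc1": cc1, "cm1": cm1, "cc2": cc2, "cm2": cm2,
                   "cf1": cf1, "cf2": cf2, "probs": probs}


def backward_batch(dprobs: np.ndarray, cache: dict,
                   params: NetworkParams) -> dict[str, np.ndarray]:
    """Backpropagate a gradient w.r.t. the output probabilities.

    Returns a dict of gradient arrays keyed like :meth:`NetworkParams.arrays`.
    """
    dz2 = softmax_backward(dprobs, cache["probs"])
    dz1, dfc2_w, dfc2_b = fc_backward(dz2, cache["cf2"])
    dm2, dfc1_w, dfc1_b = fc_backward(dz1, cache["cf1"])
    dc2, g_m2 = _layer_backward(dm2, cache["cm2"], params.mdlstm2)
    dm1, dconv2_w, dconv2_b = conv3x3_backward(dc2, cache["cc2"])
    dc1, g_m1 = _layer_backward(dm1, cache["cm1"], params.mdlstm1)
    _, dconv1_w, dconv1_b = conv3x3_backward(dc1, cache["cc1"])

    grads = {"conv1/w": dconv1_w, "conv1/b": dconv1_b,
             "conv2/w": dconv2_w, "conv2/b": dconv2_b,
             "fc_hidden/w": dfc1_w, "fc_hidden/b": dfc1_b,
             "fc_out/w": dfc2_w, "fc_out/b": dfc2_b}
    for li, gl in (("mdlstm1", g_m1), ("mdlstm2", g_m2)):
        for d, g in enumerate(gl):
            for arr in ("wx", "wh_up", "wh_left", "bias"):
                grads[f"{li}/d{d}/{arr}"] = g[arr]
    return grads


def forward(image: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Per-pixel class probabilities for a single image.

    ``image`` is any 2D array with both sides >= 8; the output has shape
    (h, w, 2) with channels (background, cone) summing to one at each pixel.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if min(img.shape) < 8:
        raise ValueError("image sides must be >= 8 px")
    x = img.astype(params.conv1_w.dtype)[None, ..., None]
    probs, _ = forward_batch(x, params)
    return probs[0]


def count_network_multiplications(h: int, w: int, units: int = 32,
                                  hidden: int = 64) -> int:
    """Total scalar multiplications for one forward pass on an h x w image.

    Interior-pixel convention for the 3x3 convolutions (9 multiplications per
    input channel per output channel at every pixel).
    """
    if h < 1 or w < 1:
        raise ValueError("h and w must be >= 1")
    per_block = count_block_multiplications(units, 1)
    per_pixel = (9 * 1 * 1                 # conv 1 -> 1
                 + 4 * per_block           # MDLSTM layer 1
                 + 9 * 4 * units * 1       # conv 4u -> 1
                 + 4 * per_block           # MDLSTM layer 2
                 + 4 * units * hidden      # FC hidden
                 + hidden * 2)             # FC output
    return per_pixel * h * w


def save_checkpoint(path, params: NetworkParams, config: dict | None = None,
                    ) -> None:
    """Write parameters as a named-array archive plus a JSON config sidecar.

    ``path`` should end in ``.npz``; the config (units, hidden, class order,
    any training metadata) is written next to it as ``<path>.json``.
    """
    arrays = {name: arr for name, arr in params.arrays()}
    np.savez(path, **arrays)
    meta = {"units": params.units, "hidden": params.hidden,
            "class_order": ["background", "cone"]}
    if config:
        meta.update(config)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path) -> NetworkParams:
    """Load a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as npz:
        data = {k: npz[k] for k in npz.files}

    def blocks(prefix):
        return [BlockWeights(wx=data[f"{prefix}/d{d}/wx"],
                             wh_up=data[f"{prefix}/d{d}/wh_up"],
                             wh_left=data[f"{prefix}/d{d}/wh_left"],
                             bias=data[f"{prefix}/d{d}/bias"])
                for d in range(4)]

    return NetworkParams(
        conv1_w=data["conv1/w"], conv1_b=data["conv1/b"],
        mdlstm1=blocks("mdlstm1"),
        conv2_w=data["conv2/w"], conv2_b=data["conv2/b"],
        mdlstm2=blocks("mdlstm2"),
        fc1_w=data["fc_hidden/w"], fc1_b=data["fc_hidden/b"],
        fc2_w=data["fc_out/w"], fc2_b=data["fc_out/b"],
    )
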