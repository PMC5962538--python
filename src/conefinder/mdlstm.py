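"""Two-dimensional multidimensional LSTM (MDLSTM) blocks and layers.

A 2D MDLSTM block scans an image in raster order, computing at each pixel a
hidden vector from the current pixel's features and the hidden/cell states of
its two causal predecessors (the pixel above and the pixel to the left).
Scanning the image under the four 90-degree rotations and concatenating the
results gives every output feature access to context from the whole image --
the property that motivates recurrent over purely convolutional
segmentation of retinal mosaics, where a patch in isolation is ambiguous.

Gate algebra per pixel (sigma = logistic, * = element-wise):

    i  = sigma(Wi x + Ui h_up + Vi h_left + bi)      input gate
    f1 = sigma(...)                                  forget gate, up
    f2 = sigma(...)                                  forget gate, left
    o  = sigma(...)                                  output gate
    g  = tanh(...)                                   candidate
    c  = i * g + 1/2 f1 * c_up + 1/2 f2 * c_left
    h  = o * tanh(c)

The 1/2-convex combination of predecessor cells keeps |c| <= 2 no matter how
long the scan is (|i*g| <= 1 and the forgotten part is a convex average of
bounded cells), which is what makes deep 2D scans trainable: plain additive
2D-LSTM cell updates grow without bound along the diagonal.

Missing neighbours (first row/column) contribute zero vectors for both h and
c. The production scan (:func:`block_scan`) is vectorised over anti-diagonal
wavefronts; :func:`block_scan_naive` is a literal per-pixel recursion kept as
an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "GATES",
    "BlockWeights",
    "block_scan",
    "block_scan_naive",
    "layer_scan",
    "count_block_multiplications",
]

#: Fixed gate order used in all packed arrays.
GATES = ("i", "f1", "f2", "o", "g")


@dataclass
class BlockWeights:
    """Learnable parameters of one directional MDLSTM block.

    Arrays are packed with the five gates side by side along the last axis in
    the order :data:`GATES`.

    Attributes
    ----------
    wx : (k, 5u) input weights (five u x k matrices, transposed and packed)
    wh_up : (u, 5u) recurrent weights from the predecessor above
    wh_left : (u, 5u) recurrent weights from the predecessor to the left
    bias : (5u,) biases
    """

    wx: np.ndarray
    wh_up: np.ndarray
    wh_left: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        u = self.units
        if self.wx.ndim != 2 or self.wx.shape[1] != 5 * u:
            raise ValueError("wx must have shape (k, 5u)")
        if self.wh_left.shape != (u, 5 * u) or self.bias.shape != (5 * u,):
            raise ValueError("inconsistent BlockWeights shapes")
        for name in ("wx", "wh_up", "wh_left", "bias"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @property
    def units(self) -> int:
        return self.wh_up.shape[0]

    @property
    def channels(self) -> int:
        return self.wx.shape[0]

    def gate(self, array: str, name: str) -> np.ndarray:
        """View of one gate's slice of a packed array ('i','f1','f2','o','g')."""
        u = self.units
        idx = GATES.index(name)
        return getattr(self, array)[..., idx * u:(idx + 1) * u]

    @classmethod
    def random(cls, units: int, channels: int, rng: np.random.Generator,
               sd: float = 0.25, dtype=np.float32) -> "BlockWeights":
        """Gaussian-initialised weights (zero biases)."""
        return cls(
            wx=rng.normal(0.0, sd, (channels, 5 * units)).astype(dtype),
            wh_up=rng.normal(0.0, sd, (units, 5 * units)).astype(dtype),
            wh_left=rng.normal(0.0, sd, (units, 5 * units)).astype(dtype),
            bias=np.zeros(5 * units, dtype=dtype),
        )

    @classmethod
    def zeros(cls, units: int, channels: int, dtype=np.float32) -> "BlockWeights":
        return cls(
            wx=np.zeros((channels, 5 * units), dtype=dtype),
            wh_up=np.zeros((units, 5 * units), dtype=dtype),
            wh_left=np.zeros((units, 5 * units), dtype=dtype),
            bias=np.zeros(5 * units, dtype=dtype),
        )


def count_block_multiplications(u: int, k: int) -> int:
    """Scalar multiplications for one block application to a single pixel.

    Five input matrix-vector products (5*u*k), ten recurrent matrix-vector
    products (10*u^2), and six element-wise products per unit: i*g, the two
    halvings and cell products 1/2*f1*c_up and 1/2*f2*c_left, and o*tanh(c).
    """
    if u < 1 or k < 1:
        raise ValueError("u and k must be >= 1")
    return 5 * u * k + 10 * u * u + 6 * u


def _diagonal(t: int, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of anti-diagonal t (i + j == t) in scan order."""
    i0 = max(0, t - w + 1)
    i1 = min(t, h - 1)
    ii = np.arange(i0, i1 + 1)
    return ii, t - ii


def _scan_forward(x: np.ndarray, w: BlockWeights, want_cache: bool = False):
    """Raster-order scan of a batched image ``x`` (B, h, w, k).

    Returns the hidden grid H (B, h, w, u) and, when requested, the cache of
    intermediate quantities needed by :func:`_scan_backward`.
    """
    B, h, wd, k = x.shape
    u = w.units
    dtype = np.result_type(x.dtype, w.wx.dtype)
    pre = x.reshape(-1, k) @ w.wx + w.bias
    pre = pre.reshape(B, h, wd, 5 * u)

    H = np.zeros((B, h, wd, u), dtype=dtype)
    C = np.zeros_like(H)
    if want_cache:
        GI = np.empty_like(H)
        F1 = np.empty_like(H)
        F2 = np.empty_like(H)
        O = np.empty_like(H)
        G = np.empty_like(H)
        TC = np.empty_like(H)

    for t in range(h + wd - 1):
        ii, jj = _diagonal(t, h, wd)
        L = ii.size
        hu = np.zeros((B, L, u), dtype=dtype)
        cu = np.zeros((B, L, u), dtype=dtype)
        m = ii > 0
        if m.any():
            hu[:, m] = H[:, ii[m] - 1, jj[m]]
            cu[:, m] = C[:, ii[m] - 1, jj[m]]
        hl = np.zeros((B, L, u), dtype=dtype)
        cl = np.zeros((B, L, u), dtype=dtype)
        m = jj > 0
        if m.any():
            hl[:, m] = H[:, ii[m], jj[m] - 1]
            cl[:, m] = C[:, ii[m], jj[m] - 1]

        a = pre[:, ii, jj] + hu @ w.wh_up + hl @ w.wh_left
        gi = expit(a[..., :u])
        f1 = expit(a[..., u:2 * u])
        f2 = expit(a[..., 2 * u:3 * u])
        o = expit(a[..., 3 * u:4 * u])
        g = np.tanh(a[..., 4 * u:])
        c = gi * g + 0.5 * (f1 * cu + f2 * cl)
        tc = np.tanh(c)
        H[:, ii, jj] = o * tc
        C[:, ii, jj] = c
        if want_cache:
            GI[:, ii, jj] = gi
            F1[:, ii, jj] = f1
            F2[:, ii, jj] = f2
            O[:, ii, jj] = o
            G[:, ii, jj] = g
            TC[:, ii, jj] = tc

    if not np.all(np.isfinite(H)):
        bad = np.argwhere(~np.isfinite(H))[0]
        raise FloatingPointError(f"non-finite activation at (b,i,j,u)={tuple(bad)}")
    if not want_cache:
        return H, None
    cache = {"x": x, "H": H, "C": C, "GI": GI, "F1": F1, "F2": F2,
             "O": O, "G": G, "TC": TC}
    return H, cache


def _scan_backward(dH: np.ndarray, cache: dict, w: BlockWeights):
    """Reverse-mode gradients of the raster scan.

    Parameters
    ----------
    dH : gradient of the loss w.r.t. the scan output H, (B, h, w, u).

    Returns ``(dx, grads)`` where ``grads`` has keys wx, wh_up, wh_left, bias.
    """
    x, H, C = cache["x"], cache["H"], cache["C"]
    GI, F1, F2 = cache["GI"], cache["F1"], cache["F2"]
    O, G, TC = cache["O"], cache["G"], cache["TC"]
    B, h, wd, u = H.shape
    dtype = H.dtype

    Gh = np.ascontiguousarray(dH, dtype=dtype).copy()
    Gc = np.zeros_like(Gh)
    DA = np.empty((B, h, wd, 5 * u), dtype=dtype)

    for t in range(h + wd - 2, -1, -1):
        ii, jj = _diagonal(t, h, wd)
        L = ii.size
        gh = Gh[:, ii, jj]
        tc = TC[:, ii, jj]
        o = O[:, ii, jj]
        gi = GI[:, ii, jj]
        f1 = F1[:, ii, jj]
        f2 = F2[:, ii, jj]
        g = G[:, ii, jj]

        gc = Gc[:, ii, jj] + gh * o * (1.0 - tc * tc)
        cu = np.zeros((B, L, u), dtype=dtype)
        mu = ii > 0
        if mu.any():
            cu[:, mu] = C[:, ii[mu] - 1, jj[mu]]
        cl = np.zeros((B, L, u), dtype=dtype)
        ml = jj > 0
        if ml.any():
            cl[:, ml] = C[:, ii[ml], jj[ml] - 1]

        da = np.empty((B, L, 5 * u), dtype=dtype)
        da[..., :u] = gc * g * gi * (1.0 - gi)
        da[..., u:2 * u] = gc * 0.5 * cu * f1 * (1.0 - f1)
        da[..., 2 * u:3 * u] = gc * 0.5 * cl * f2 * (1.0 - f2)
        da[..., 3 * u:4 * u] = gh * tc * o * (1.0 - o)
        da[..., 4 * u:] = gc * gi * (1.0 - g * g)
        DA[:, ii, jj] = da

        if mu.any():
            Gh[:, ii[mu] - 1, jj[mu]] += (da @ w.wh_up.T)[:, mu]
            Gc[:, ii[mu] - 1, jj[mu]] += (gc * 0.5 * f1)[:, mu]
        if ml.any():
            Gh[:, ii[ml], jj[ml] - 1] += (da @ w.wh_left.T)[:, ml]
            Gc[:, ii[ml], jj[ml] - 1] += (gc * 0.5 * f2)[:, ml]

    k = x.shape[-1]
    DA2 = DA.reshape(-1, 5 * u)
    # predecessor hidden grids: H shifted down / right with zero fill
    HU = np.zeros_like(H)
    HU[:, 1:] = H[:, :-1]
    HL = np.zeros_like(H)
    HL[:, :, 1:] = H[:, :, :-1]
    grads = {
        "wx": x.reshape(-1, k).T @ DA2,
        "wh_up": HU.reshape(-1, u).T @ DA2,
        "wh_left": HL.reshape(-1, u).T @ DA2,
        "bias": DA2.sum(axis=0),
    }
    dx = (DA2 @ w.wx.T).reshape(x.shape)
    return dx, grads


def _rot_batch(x: np.ndarray, k: int) -> np.ndarray:
    """Rotate the spatial axes (1, 2) of a batched grid by k * 90 degrees."""
    return np.rot90(x, k, axes=(1, 2))


def block_scan(image: np.ndarray, weights: BlockWeights,
               direction: int = 0) -> np.ndarray:
    """Apply one MDLSTM block along a chosen scan direction.

    The image is rotated by ``direction`` quarter-turns, scanned top-to-bottom
    left-to-right, and the hidden grid is rotated back, so output features stay
    aligned with input pixels.

    Parameters
    ----------
    image : (h, w, k) feature image (a 2D array is treated as k=1).
    weights : block parameters with matching channel count.
    direction : number of 90-degree rotations in {0, 1, 2, 3}.

    Returns the (h, w, u) feature image.
    """
    if direction not in (0, 1, 2, 3):
        raise ValueError("direction must be in {0, 1, 2, 3}")
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[..., None]
    if img.ndim != 3:
        raise ValueError("image must be (h, w, k)")
    if img.shape[-1] != weights.channels:
        raise ValueError("image channels do not match weights")
    x = _rot_batch(img[None], direction)
    H, _ = _scan_forward(x, weights)
    return _rot_batch(H, -direction)[0]


def block_scan_naive(image: np.ndarray, weights: BlockWeights,
                     direction: int = 0) -> np.ndarray:
    """Literal per-pixel recursion; reference implementation for testing."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[..., None]
    x = np.rot90(img, direction, axes=(0, 1))
    h, wd, k = x.shape
    u = weights.units
    dtype = np.result_type(x.dtype, weights.wx.dtype)
    H = np.zeros((h, wd, u), dtype=dtype)
    C = np.zeros((h, wd, u), dtype=dtype)
    zero = np.zeros(u, dtype=dtype)
    for i in range(h):
        for j in range(wd):
            hu = H[i - 1, j] if i > 0 else zero
            hl = H[i, j - 1] if j > 0 else zero
            cu = C[i - 1, j] if i > 0 else zero
            cl = C[i, j - 1] if j > 0 else zero
            a = (x[i, j] @ weights.wx + hu @ weights.wh_up
                 + hl @ weights.wh_left + weights.bias)
            gi = expit(a[:u])
            f1 = expit(a[u:2 * u])
            f2 = expit(a[2 * u:3 * u])
            o = expit(a[3 * u:4 * u])
            g = np.tanh(a[4 * u:])
            C[i, j] = gi * g + 0.5 * (f1 * cu + f2 * cl)
            H[i, j] = o * np.tanh(C[i, j])
    return np.rot90(H, -direction, axes=(0, 1))


def layer_scan(image: np.ndarray, weights4) -> np.ndarray:
    """One MDLSTM layer: four directional blocks, outputs concatenated.

    ``weights4`` is a sequence of four :class:`BlockWeights` applied with
    directions 0..3 in that fixed order; the result has 4u channels.
    """
    weights4 = list(weights4)
    if len(weights4) != 4:
        raise ValueError("layer_scan needs exactly four blocks")
    u = weights4[0].units
    k = weights4[0].channels
    for w in weights4[1:]:
        if w.units != u or w.channels != k:
            raise ValueError("all four blocks must share units and channels")
    outs = [block_scan(image, w, d) for d, w in enumerate(weights4)]
    return np.concatenate(outs, axis=-1)
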