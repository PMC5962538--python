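"""Cone centroid recovery from probability maps.

Recovery applies five steps, in order, to the cone-probability channel:

1. smooth with a Gaussian filter of *variance* sigma (note: the parameter is
   the variance in px^2, so the filter's standard deviation is sqrt(sigma) --
   kept this way deliberately; do not pass a standard deviation);
2. find local maxima over centred 7 x 7 neighbourhoods of the smoothed map
   (plateau ties resolved to the topmost, then leftmost pixel);
3. reject maxima whose smoothed value falls below a threshold T;
4. reject maxima within 7 px of the image border;
5. merge centroids less than 8 px apart into single points (single-linkage
   clusters replaced by their mean, iterated until all pairs are >= 8 px
   apart).

Healthy and diseased mosaics need different (sigma, T): sparse, low-contrast
maps require a more tolerant threshold. Adaptive localisation first runs a
jointly calibrated pair to estimate cone density, classifies the image as
dense (> 0.0011 cones/px) or sparse, then reprocesses the map with the
regime-specific pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from . import evaluation

__all__ = [
    "RecoveryParams",
    "recover_centroids",
    "classify_density",
    "adaptive_localise",
    "calibrate",
    "DEFAULT_SIGMA_GRID",
    "DEFAULT_T_GRID",
]

DEFAULT_SIGMA_GRID: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
DEFAULT_T_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


@dataclass(frozen=True)
class RecoveryParams:
    """Recovery parameters.

    ``sigma`` is the Gaussian filter *variance* in px^2 and ``threshold`` the
    probability cut-off in [0, 1]; the remaining fields are fixed constants of
    the procedure (raw pixel units, independent of field of view).
    """

    sigma: float
    threshold: float
    maxima_window: int = 7
    border_margin: int = 7
    merge_distance: float = 8.0
    density_cutoff: float = 0.0011

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma (variance) must be positive")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def _merge_close(points: np.ndarray, min_dist: float) -> np.ndarray:
    """Single-linkage merge of points closer than ``min_dist``, iterated."""
    pts = np.asarray(points, dtype=np.float64)
    while len(pts) > 1:
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        close = d < min_dist
        if close.sum() <= len(pts):            # only the diagonal: done
            break
        parent = list(range(len(pts)))         # union-find on the <8px graph

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                if close[a, b]:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
        roots = np.array([find(a) for a in range(len(pts))])
        merged = np.array([pts[roots == r].mean(axis=0)
                           for r in np.unique(roots)])
        if len(merged) == len(pts):
            break
        pts = merged
    return pts


def recover_centroids(prob: np.ndarray, params: RecoveryParams) -> np.ndarray:
    """Apply the five recovery steps to a cone-probability map.

    ``prob`` is the (h, w) cone channel with values in [0, 1]. Returns an
    (n, 2) float array of (row, col) centroids; an empty result is legal.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.ndim != 2:
        raise ValueError("prob must be a 2D cone-probability map")
    h, w = prob.shape
    sm = ndimage.gaussian_filter(prob, sigma=np.sqrt(params.sigma))

    win = params.maxima_window
    mf = ndimage.maximum_filter(sm, size=win, mode="constant", cval=-np.inf)
    cand = sm >= mf
    # Adjacent candidate pixels fall in each other's window, hence share the
    # window maximum: each connected candidate component is a constant
    # plateau. Keep its topmost-then-leftmost pixel.
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    points = []
    if n:
        rows, cols = np.nonzero(cand)          # row-major: top-left first
        seen = set()
        for r, c in zip(rows, cols):
            lab = labels[r, c]
            if lab not in seen:
                seen.add(lab)
                points.append((float(r), float(c)))
    points = np.array(points, dtype=np.float64).reshape(-1, 2)

    if len(points):
        vals = sm[points[:, 0].astype(int), points[:, 1].astype(int)]
        points = points[vals >= params.threshold]
    if len(points):
        m = params.border_margin
        dist = np.minimum(np.minimum(points[:, 0], points[:, 1]),
                          np.minimum(h - 1 - points[:, 0],
                                     w - 1 - points[:, 1]))
        points = points[dist >= m]
    if len(points):
        points = _merge_close(points, params.merge_distance)
    return points


def classify_density(centroids: np.ndarray, image_shape: tuple[int, int],
                     cutoff: float = 0.0011) -> str:
    """'dense' iff strictly more than ``cutoff`` cones per pixel, else 'sparse'."""
    h, w = image_shape
    n = len(np.asarray(centroids).reshape(-1, 2))
    return "dense" if n / (h * w) > cutoff else "sparse"


def adaptive_localise(prob: np.ndarray, params_b: RecoveryParams,
                      params_h: RecoveryParams,
                      params_s: RecoveryParams) -> np.ndarray:
    """Two-pass localisation with the dense/sparse switch.

    A first pass with the jointly calibrated ``params_b`` estimates density;
    the map is then reprocessed with ``params_h`` (dense) or ``params_s``
    (sparse) and that second pass is returned.
    """
    first = recover_centroids(prob, params_b)
    regime = classify_density(first, prob.shape, params_b.density_cutoff)
    second = params_h if regime == "dense" else params_s
    return recover_centroids(prob, second)


def _mean_dice(prob_maps, truth_sets, params: RecoveryParams) -> float:
    scores = []
    for prob, truth in zip(prob_maps, truth_sets):
        est = recover_centroids(prob, params)
        res = evaluation.match(est, truth)
        if res.tp + res.fp + res.fn == 0:
            scores.append(1.0)
        else:
            scores.append(evaluation.dice(res))
    return float(np.mean(scores))


def calibrate(prob_maps, truth_sets,
              sigma_grid=DEFAULT_SIGMA_GRID,
              t_grid=DEFAULT_T_GRID,
              base: RecoveryParams | None = None) -> RecoveryParams:
    """Grid-search (sigma, T) maximising mean detection Dice.

    ``prob_maps`` and ``truth_sets`` are the validation subset to optimise
    over (pass only healthy maps for (sigma_h, T_h), only diseased for
    (sigma_s, T_s), or everything for (sigma_b, T_b)). Ties are broken toward
    the smallest sigma, then the smallest T.
    """
    prob_maps = list(prob_maps)
    truth_sets = list(truth_sets)
    if not prob_maps or len(prob_maps) != len(truth_sets):
        raise ValueError("need a non-empty, matched validation subset")
    if base is None:
        base = RecoveryParams(sigma=1.0, threshold=0.5)
    best = None
    best_score = -np.inf
    for sigma in sorted(sigma_grid):
        for t in sorted(t_grid):
            params = replace(base, sigma=float(sigma), threshold=float(t))
            score = _mean_dice(prob_maps, truth_sets, params)
            if score > best_score:       # strict: ties keep smallest sigma, T
                best_score = score
                best = params
    return best
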