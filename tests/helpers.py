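"""Independent brute-force references used by the test suite.

These implementations apply the definitions literally (per-pixel loops, full
pair enumeration) and deliberately share no code with the package's
vectorised implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def brute_force_recover(prob: np.ndarray, sigma_var: float, threshold: float,
                        window: int = 7, border: int = 7,
                        merge_dist: float = 8.0) -> np.ndarray:
    """Literal application of the five centroid-recovery rules."""
    sm = ndimage.gaussian_filter(np.asarray(prob, float),
                                 sigma=np.sqrt(sigma_var))
    h, w = sm.shape
    half = window // 2
    maxima = []
    for r in range(h):
        for c in range(w):
            rlo, rhi = max(r - half, 0), min(r + half, h - 1)
            clo, chi = max(c - half, 0), min(c + half, w - 1)
            win = sm[rlo:rhi + 1, clo:chi + 1]
            if sm[r, c] < win.max():
                continue
            # plateau tie-break: topmost-then-leftmost pixel of the connected
            # component of equal-valued window maxima
            is_first = True
            for rr in range(h):
                done = False
                for cc in range(w):
                    if (rr, cc) == (r, c):
                        done = True
                        break
                    if sm[rr, cc] == sm[r, c] and _connected(sm, (rr, cc), (r, c)):
                        is_first = False
                        done = True
                        break
                if done:
                    break
            if is_first:
                maxima.append((float(r), float(c)))
    pts = [p for p in maxima if sm[int(p[0]), int(p[1])] >= threshold]
    pts = [p for p in pts
           if min(p[0], p[1], h - 1 - p[0], w - 1 - p[1]) >= border]
    pts = np.array(pts, float).reshape(-1, 2)
    # iterated single-linkage merge
    while len(pts) > 1:
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= merge_dist:
            break
        groups = _single_linkage(pts, merge_dist)
        pts = np.array([pts[g].mean(axis=0) for g in groups])
    return pts


def _connected(sm, a, b):
    """8-connectivity between two equal-valued pixels through equal values."""
    mask = sm == sm[a]
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), int))
    return labels[a] == labels[b]


def _single_linkage(pts, dist):
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) < dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def greedy_match_oracle(est: np.ndarray, truth: np.ndarray, tolerance: float):
    """Full pair enumeration; greedy one-to-one by ascending distance.

    Returns (tp, fp, fn, pairs).
    """
    est = np.asarray(est, float).reshape(-1, 2)
    truth = np.asarray(truth, float).reshape(-1, 2)
    cand = []
    for a in range(len(truth)):
        for b in range(len(est)):
            d = float(np.hypot(*(truth[a] - est[b])))
            if d <= tolerance:
                cand.append((d, a, b))
    cand.sort()
    used_t, used_e, pairs = set(), set(), []
    for d, a, b in cand:
        if a not in used_t and b not in used_e:
            used_t.add(a)
            used_e.add(b)
            pairs.append((a, b))
    tp = len(pairs)
    return tp, len(est) - tp, len(truth) - tp, pairs


def disk_pixel_count(r0: float, c0: float, radius: float,
                     shape: tuple[int, int]) -> int:
    """Brute-force count of integer lattice points within ``radius``."""
    h, w = shape
    n = 0
    for r in range(h):
        for c in range(w):
            if (r - r0) ** 2 + (c - c0) ** 2 <= radius ** 2:
                n += 1
    return n
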