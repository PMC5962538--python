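"""Synthetic split-detection retinal images with exact ground truth.

Clinical AOSLO split-detection data carry patient-information restrictions and
are not redistributable, so this module generates images that emulate their
salient features: cone inner segments appear as adjacent dark/bright lobe
pairs (a horizontal intensity dipole) on a noisy, slowly varying background.
Two regimes are modelled:

* ``healthy`` -- dense, quasi-hexagonal mosaics with high occupancy and
  contrast (small cone spacing);
* ``disease`` -- sparse, irregular, low-contrast mosaics such as those seen
  in Stargardt disease (large spacing, heavy cone loss, more noise).

Every sample comes with the exact centroid list and the disk segmentation
mask derived from it, so detection pipelines can be scored against a perfect
gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MosaicSpec",
    "SyntheticSample",
    "EmptyMosaicError",
    "HEALTHY_RANGES",
    "DISEASE_RANGES",
    "generate_centroids",
    "render_image",
    "make_mask",
    "generate_dataset",
]

# Per-regime parameter ranges used by generate_dataset. Disease occupancy and
# spacing are chosen so that the cone density stays below the 0.0011 cones/px
# dense/sparse cut-off even before border trimming (triangular-lattice density
# is occupancy / (spacing^2 * sqrt(3)/2)), while healthy mosaics sit well
# above it.
HEALTHY_RANGES: dict[str, tuple[float, float]] = {
    "spacing": (9.0, 12.0),
    "jitter": (0.04, 0.08),
    "occupancy": (0.92, 1.0),
    "lobe_sigma": (1.6, 2.4),
    "lobe_offset": (3.0, 4.0),
    "contrast": (0.8, 1.0),
    "noise_sigma": (0.03, 0.06),
    "background_sigma": (0.05, 0.10),
}
DISEASE_RANGES: dict[str, tuple[float, float]] = {
    "spacing": (20.0, 26.0),
    "jitter": (0.06, 0.12),
    "occupancy": (0.18, 0.34),
    "lobe_sigma": (2.0, 3.0),
    "lobe_offset": (4.0, 6.0),
    "contrast": (0.45, 0.7),
    "noise_sigma": (0.06, 0.10),
    "background_sigma": (0.08, 0.14),
}


class EmptyMosaicError(ValueError):
    """Raised when a spec admits no lattice site inside the frame."""


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of one synthetic cone mosaic.

    Coordinates are (row, col), 0-based, with pixel centres at integers.

    Parameters
    ----------
    height, width : int
        Frame size in pixels.
    spacing : float
        Mean nearest-neighbour cone distance in pixels (lattice pitch).
    jitter : float
        Positional noise as a fraction of ``spacing``. Displacements are
        Gaussian with sd ``jitter * spacing`` and norm-clipped at
        ``jitter * spacing`` so that neighbours stay at least
        ``spacing * (1 - 2 * jitter)`` apart.
    occupancy : float
        Fraction of lattice sites retained, in (0, 1].
    lobe_sigma : float
        Gaussian scale of each dipole lobe, pixels.
    lobe_offset : float
        Separation between the dark and bright lobe centres, pixels.
    contrast : float
        Peak lobe amplitude in intensity units (before rescaling).
    noise_sigma : float
        Additive white Gaussian noise scale.
    background_sigma : float
        Amplitude of the smooth background texture (low-pass filtered noise).
    seed : int
        RNG seed; identical spec + seed reproduces the sample bit-exactly.
    """

    height: int
    width: int
    spacing: float = 10.0
    jitter: float = 0.05
    occupancy: float = 1.0
    lobe_sigma: float = 2.0
    lobe_offset: float = 3.5
    contrast: float = 1.0
    noise_sigma: float = 0.04
    background_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be positive")
        if not self.spacing > 2:
            raise ValueError("spacing must exceed 2 px")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must lie in (0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        for name in ("lobe_sigma", "lobe_offset", "contrast", "noise_sigma",
                     "background_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lobe_sigma == 0:
            raise ValueError("lobe_sigma must be positive")

    @property
    def disk_radius(self) -> float:
        """Mask disk radius: 0.35 x spacing, at least 2 px.

        Chosen so the dilated disk covers most of the cone while leaving its
        border visible in the rendered image.
        """
        return max(2.0, 0.35 * self.spacing)


@dataclass
class SyntheticSample:
    """One generated image with its ground truth."""

    image: np.ndarray          # (h, w) float32 in [0, 1]
    centroids: np.ndarray      # (n, 2) float64, (row, col)
    mask: np.ndarray           # (h, w, 2) uint8 one-hot (background, cone)
    disk_radius: float
    spec: MosaicSpec
    regime: str = "healthy"

    @property
    def density(self) -> float:
        """Cones per pixel."""
        h, w = self.image.shape
        return len(self.centroids) / (h * w)


def generate_centroids(spec: MosaicSpec,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw cone centroids from a jittered, thinned triangular lattice.

    Sites form a hexagonal-packing lattice of pitch ``spacing`` (row pitch
    ``spacing * sqrt(3)/2``, alternate rows offset by half a pitch), are
    perturbed by clipped isotropic Gaussian noise, independently retained
    with probability ``occupancy``, and finally trimmed of points within
    ``spec.disk_radius`` of the frame border.

    Returns an (n, 2) array of (row, col) positions.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    s = spec.spacing
    dy = s * np.sqrt(3.0) / 2.0
    rows = np.arange(0.0, spec.height, dy)
    if rows.size == 0 or np.arange(0.0, spec.width, s).size == 0:
        raise EmptyMosaicError("spec admits no lattice site inside the frame")
    pts = []
    for irow, r in enumerate(rows):
        offset = (s / 2.0) if irow % 2 else 0.0
        cols = np.arange(offset, spec.width, s)
        pts.append(np.column_stack([np.full_like(cols, r), cols]))
    points = np.concatenate(pts, axis=0)
    if points.shape[0] == 0:
        raise EmptyMosaicError("spec admits no lattice site inside the frame")

    if spec.jitter > 0:
        sd = spec.jitter * s
        disp = rng.normal(0.0, sd, size=points.shape)
        norm = np.linalg.norm(disp, axis=1, keepdims=True)
        scale = np.minimum(1.0, sd / np.maximum(norm, 1e-12))
        points = points + disp * scale
    else:
        rng.normal(0.0, 1.0, size=points.shape)  # keep stream alignment

    r_i = spec.disk_radius

    def _trim(pts):
        inside = ((pts[:, 0] >= r_i) & (pts[:, 0] <= spec.height - 1 - r_i)
                  & (pts[:, 1] >= r_i) & (pts[:, 1] <= spec.width - 1 - r_i))
        return pts[inside]

    if len(_trim(points)) == 0:
        raise EmptyMosaicError(
            "no lattice site survives the border margin; frame too small "
            "for this spacing")
    keep = rng.random(points.shape[0]) < spec.occupancy
    return _trim(points[keep])


def _add_lobe(canvas: np.ndarray, r0: float, c0: float, amp: float,
              sigma: float) -> None:
    """Accumulate one Gaussian lobe onto the canvas (local window)."""
    h, w = canvas.shape
    half = int(np.ceil(4 * sigma))
    rlo, rhi = int(np.floor(r0)) - half, int(np.ceil(r0)) + half
    clo, chi = int(np.floor(c0)) - half, int(np.ceil(c0)) + half
    rlo, rhi = max(rlo, 0), min(rhi, h - 1)
    clo, chi = max(clo, 0), min(chi, w - 1)
    if rlo > rhi or clo > chi:
        return
    rr = np.arange(rlo, rhi + 1, dtype=np.float64)[:, None]
    cc = np.arange(clo, chi + 1, dtype=np.float64)[None, :]
    canvas[rlo:rhi + 1, clo:chi + 1] += amp * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2))


def render_image(centroids: np.ndarray, spec: MosaicSpec,
                 rng: np.random.Generator | None = None,
                 normalise: bool = True) -> np.ndarray:
    """Render a split-detection-like image from centroid positions.

    Each cone is a horizontal dipole: a negative Gaussian lobe at
    ``(r, c - lobe_offset/2)`` and a positive one at ``(r, c + lobe_offset/2)``,
    both of amplitude ``contrast`` and scale ``lobe_sigma``, mimicking the
    left-dark/right-bright shading the differential detector produces. Dipoles
    are summed onto a smooth background texture (white noise low-pass filtered
    at ``4 * lobe_sigma``) and degraded with additive white Gaussian noise.

    With ``normalise=True`` (default) intensities are affinely rescaled to
    [0, 1]; ``normalise=False`` returns the raw sum, which is linear in the
    centroid list.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    centroids = np.asarray(centroids, dtype=np.float64).reshape(-1, 2)
    if centroids.size and (
            centroids[:, 0].min() < 0 or centroids[:, 1].min() < 0
            or centroids[:, 0].max() > spec.height - 1
            or centroids[:, 1].max() > spec.width - 1):
        raise ValueError("centroids must lie inside the frame")

    canvas = np.zeros((spec.height, spec.width), dtype=np.float64)
    if spec.background_sigma > 0:
        bg = rng.normal(0.0, 1.0, canvas.shape)
        bg = gaussian_filter(bg, sigma=4.0 * spec.lobe_sigma)
        sd = bg.std()
        if sd > 0:
            canvas += bg * (spec.background_sigma / sd)
    for r0, c0 in centroids:
        _add_lobe(canvas, r0, c0 - spec.lobe_offset / 2.0, -spec.contrast,
                  spec.lobe_sigma)
        _add_lobe(canvas, r0, c0 + spec.lobe_offset / 2.0, spec.contrast,
                  spec.lobe_sigma)
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, canvas.shape)

    if normalise:
        lo, hi = canvas.min(), canvas.max()
        if hi > lo:
            canvas = (canvas - lo) / (hi - lo)
        else:
            canvas = np.zeros_like(canvas)
    return canvas.astype(np.float32)


def make_mask(centroids: np.ndarray, disk_radius: float,
              shape: tuple[int, int]) -> np.ndarray:
    """Dilate centroids to disks, producing a one-hot segmentation mask.

    A pixel belongs to the cone class iff its Euclidean distance to some
    centroid is <= ``disk_radius``. Returns an (h, w, 2) uint8 array with
    channel order (background, cone).
    """
    if disk_radius < 0.5:
        raise ValueError("disk_radius must be at least 0.5 px")
    h, w = shape
    centroids = np.asarray(centroids, dtype=np.float64).reshape(-1, 2)
    if centroids.size and (
            centroids[:, 0].min() < 0 or centroids[:, 1].min() < 0
            or centroids[:, 0].max() > h - 1 or centroids[:, 1].max() > w - 1):
        raise ValueError("centroid outside mask shape")
    cone = np.zeros((h, w), dtype=bool)
    half = int(np.ceil(disk_radius))
    for r0, c0 in centroids:
        rlo = max(int(np.floor(r0)) - half, 0)
        rhi = min(int(np.ceil(r0)) + half, h - 1)
        clo = max(int(np.floor(c0)) - half, 0)
        chi = min(int(np.ceil(c0)) + half, w - 1)
        rr = np.arange(rlo, rhi + 1, dtype=np.float64)[:, None]
        cc = np.arange(clo, chi + 1, dtype=np.float64)[None, :]
        cone[rlo:rhi + 1, clo:chi + 1] |= (
            (rr - r0) ** 2 + (cc - c0) ** 2 <= disk_radius ** 2)
    mask = np.zeros((h, w, 2), dtype=np.uint8)
    mask[..., 1] = cone
    mask[..., 0] = ~cone
    return mask


def _draw_spec(ranges: dict[str, tuple[float, float]], height: int, width: int,
               seed: int, rng: np.random.Generator) -> MosaicSpec:
    kwargs = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    return MosaicSpec(height=height, width=width, seed=seed, **kwargs)


def make_sample(spec: MosaicSpec, regime: str = "healthy") -> SyntheticSample:
    """Generate one full sample (image, centroids, mask) from a spec."""
    rng = np.random.default_rng(spec.seed)
    centroids = generate_centroids(spec, rng)
    image = render_image(centroids, spec, rng)
    mask = make_mask(centroids, spec.disk_radius, (spec.height, spec.width))
    return SyntheticSample(image=image, centroids=centroids, mask=mask,
                           disk_radius=spec.disk_radius, spec=spec,
                           regime=regime)


def generate_dataset(n_images: int, healthy_fraction: float, seed: int,
                     height: int = 128, width: int = 128,
                     spec_ranges: dict[str, dict[str, tuple[float, float]]] | None = None,
                     ) -> list[SyntheticSample]:
    """Generate a mixed healthy/disease dataset.

    ``round(n_images * healthy_fraction)`` samples come from the healthy
    (dense) regime and the rest from the disease (sparse) regime; per-image
    mosaic parameters are drawn uniformly from the regime's ranges. The same
    ``seed`` reproduces the dataset exactly.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 0 <= healthy_fraction <= 1:
        raise ValueError("healthy_fraction must lie in [0, 1]")
    ranges = spec_ranges or {"healthy": HEALTHY_RANGES, "disease": DISEASE_RANGES}
    n_healthy = int(round(n_images * healthy_fraction))
    regimes = ["healthy"] * n_healthy + ["disease"] * (n_images - n_healthy)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_images)
    samples = []
    for regime, child in zip(regimes, children):
        rng = np.random.default_rng(child)
        sample_seed = int(rng.integers(0, 2**31 - 1))
        spec = _draw_spec(ranges[regime], height, width, sample_seed, rng)
        samples.append(make_sample(spec, regime))
    return samples
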