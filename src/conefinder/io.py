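"""File I/O: images (TIFF/PNG), centroid CSVs, masks, dataset manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "save_image", "load_image",
    "save_centroids", "load_centroids",
    "save_mask", "load_mask",
    "save_manifest", "load_manifest",
]


def save_image(path, image: np.ndarray) -> None:
    """Write a grayscale image; .tif/.tiff as float32, .png as 8-bit."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        arr = np.asarray(image, dtype=np.float64)
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
        Image.fromarray((scaled * 255).round().astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=np.float32)
    img = np.asarray(Image.open(path).convert("F"), dtype=np.float32)
    return img / 255.0


def save_centroids(path, centroids: np.ndarray) -> None:
    """CSV with header ``row,col``."""
    pts = np.asarray(centroids, dtype=np.float64).reshape(-1, 2)
    pd.DataFrame(pts, columns=["row", "col"]).to_csv(path, index=False)


def load_centroids(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["row", "col"]].to_numpy(dtype=np.float64)


def save_mask(path, mask: np.ndarray) -> None:
    """Write the cone channel of a one-hot mask as a 0/255 PNG."""
    cone = mask[..., 1] if mask.ndim == 3 else mask
    Image.fromarray((np.asarray(cone) > 0).astype(np.uint8) * 255).save(path)


def load_mask(path) -> np.ndarray:
    """Read a 0/255 PNG back into an (h, w, 2) one-hot mask."""
    cone = np.asarray(Image.open(path).convert("L")) > 127
    mask = np.zeros(cone.shape + (2,), dtype=np.uint8)
    mask[..., 1] = cone
    mask[..., 0] = ~cone
    return mask


def save_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
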