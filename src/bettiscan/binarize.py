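"""Loading H&E tiles and turning them into binary masks.

Two masks drive the whole pipeline:

* the *blank* mask — near-white glass pixels, identified by a min-channel
  threshold (default 220); its complement is the tissue and its per-segment
  fraction is the non-blank ratio used to normalize segment scores;
* the *foreground* mask — hematoxylin-dark tissue, obtained by an automatic
  per-image threshold: pixel darkness is the complement of Rec.601 luminance
  and the cut maximizes between-class variance (Otsu) over the darkness of
  the non-blank pixels only, so glass never biases the split.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.filters import threshold_otsu

__all__ = [
    "DEFAULT_BLANK_LEVEL",
    "load_image",
    "blank_mask",
    "darkness",
    "binarize",
    "write_mask",
]

DEFAULT_BLANK_LEVEL = 220

# Rec.601 luminance weights, fixed for reproducibility.
_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF/BMP raster as an (H, W, 3) uint8 RGB array.

    Grayscale inputs are replicated across the three channels; alpha is
    dropped.  Raises ``ValueError`` naming the path for unreadable or
    zero-area inputs.
    """
    try:
        with Image.open(path) as img:
            rgb = img.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ValueError(f"cannot read image file: {path}") from exc
    if arr.size == 0 or arr.ndim != 3:
        raise ValueError(f"zero-area or malformed image: {path}")
    return arr


def _check_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    return arr


def blank_mask(img: np.ndarray, blank_level: int = DEFAULT_BLANK_LEVEL) -> np.ndarray:
    """True where a pixel is blank glass: min(R, G, B) >= blank_level."""
    arr = _check_rgb(img)
    if not 0 <= blank_level <= 255:
        raise ValueError(f"blank_level must lie in [0, 255], got {blank_level}")
    return arr.min(axis=2) >= blank_level


def darkness(img: np.ndarray) -> np.ndarray:
    """Per-pixel darkness: 255 minus rounded Rec.601 luminance (uint8)."""
    arr = _check_rgb(img)
    luma = np.rint(arr.astype(np.float64) @ _LUMA)
    return (255 - luma).astype(np.uint8)


def binarize(img: np.ndarray, blanks: np.ndarray) -> np.ndarray:
    """Extract the hematoxylin-dark foreground with an automatic threshold.

    The threshold t maximizes between-class variance of the darkness
    histogram restricted to non-blank pixels; a pixel is foreground iff it
    is non-blank and strictly darker than t.  A degenerate (single-valued)
    histogram falls back to t = median darkness, which leaves the
    foreground empty under the strict inequality.
    """
    arr = _check_rgb(img)
    blanks = np.asarray(blanks, dtype=bool)
    if blanks.shape != arr.shape[:2]:
        raise ValueError(
            f"blank mask shape {blanks.shape} does not match image {arr.shape[:2]}"
        )
    tissue = ~blanks
    if not tissue.any():
        return np.zeros(arr.shape[:2], dtype=bool)

    d = darkness(arr)
    vals = d[tissue]
    if vals.min() == vals.max():
        t = float(np.median(vals))
    else:
        t = float(threshold_otsu(vals, nbins=256))
    return tissue & (d > t)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as an 8-bit PNG (0 = false, 255 = true)."""
    arr = np.asarray(mask, dtype=bool)
    Image.fromarray(arr.astype(np.uint8) * 255, mode="L").save(path)
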