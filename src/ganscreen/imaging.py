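"""Grayscale image I/O and the disk/internal pixel-range convention.

On disk images are 8-bit grayscale PNG (0..255); in memory every pixel
lives in [-1, 1], the Tanh output range of the generator.  The affine map
between the two is

    disk = round( (internal + 1) / 2 * 255 )      (round half up)
    internal = disk / 255 * 2 - 1

so both endpoints are exact and a round trip changes a pixel by at most
1/255.  Color inputs are collapsed to grayscale by channel mean before
range mapping; arbitrary input sizes are resized to the working resolution
with bilinear interpolation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ValidationError
from .synthetic import ImageSample, ViewLabel

DISK_MIN, DISK_MAX = 0, 255
INTERNAL_MIN, INTERNAL_MAX = -1.0, 1.0


def to_disk(pixels: np.ndarray) -> np.ndarray:
    """[-1, 1] floats -> uint8, rounding half up so endpoints map exactly."""
    scaled = (np.asarray(pixels, dtype=np.float64) - INTERNAL_MIN) / (INTERNAL_MAX - INTERNAL_MIN)
    return np.floor(scaled * DISK_MAX + 0.5).clip(DISK_MIN, DISK_MAX).astype(np.uint8)


def from_disk(values: np.ndarray) -> np.ndarray:
    """uint8 -> [-1, 1] floats (exact at both endpoints)."""
    return np.asarray(values, dtype=np.float64) / DISK_MAX * (INTERNAL_MAX - INTERNAL_MIN) + INTERNAL_MIN


def load_image(path, resolution: int) -> ImageSample:
    """Read a PNG (or any PIL-decodable image) as an UNKNOWN-label sample.

    Multi-channel images are averaged to one channel; the result is
    bilinearly resized to resolution x resolution.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"{path}: zero-sized image")
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.shape != (resolution, resolution):
        im2 = Image.fromarray(arr).resize((resolution, resolution), Image.BILINEAR)
        arr = np.asarray(im2, dtype=np.float64)
    return ImageSample(pixels=from_disk(arr).clip(-1.0, 1.0),
                       label=ViewLabel.UNKNOWN).validate()


def save_image(sample: ImageSample, path) -> None:
    """Write an 8-bit grayscale PNG under the range convention."""
    sample.validate()
    path = Path(path)
    try:
        Image.fromarray(to_disk(sample.pixels), mode="L").save(path, format="PNG")
    except OSError as exc:
        raise OSError(f"cannot write image {path}: {exc}") from exc
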