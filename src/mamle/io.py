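"""Image and label-mask I/O.

Working representations are plain numpy arrays: a grayscale image is a 2-D
float array (``GrayImage`` carries the source bit depth alongside), a label
mask is a 2-D non-negative integer array where 0 is background and positive
labels are objects.  Files are single-channel TIFF or PNG; multi-channel
inputs are collapsed by channel averaging.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = ["GrayImage", "read_image", "write_image", "write_label_mask", "read_label_mask"]

MIN_IMAGE_SIDE = 16


@dataclasses.dataclass
class GrayImage:
    """A 2-D grayscale raster with its source bit depth (8 or 16)."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D array")
        if min(self.pixels.shape) < MIN_IMAGE_SIDE:
            raise ValueError(f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("image values must be finite and non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


def read_image(path: str | Path) -> GrayImage:
    """Read an 8/16-bit TIFF or PNG as a grayscale image.

    Multi-channel images are converted by averaging channels (luminance
    preserving for equal-weight channels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported pixel type {arr.dtype} in {path}; expected uint8/uint16")
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=-1)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return GrayImage(arr.astype(np.float64), bit_depth=depth)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a grayscale image at its source bit depth (TIFF or PNG)."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    data = np.clip(np.rint(img.pixels), 0, img.max_value).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as a 16-bit single-channel TIFF (lossless)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must be a 2-D integer array")
    if mask.min() < 0:
        raise ValueError("label mask must be non-negative")
    if mask.max() > 65535:
        raise ValueError(f"label overflow: {mask.max()} labels exceed the 16-bit limit (65535)")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a label mask written by :func:`write_label_mask`."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError("label mask file must be single-channel")
    return arr.astype(np.int32)
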