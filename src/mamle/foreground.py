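"""Foreground / background separation.

Fluorescence images (bright cells, dark background) are thresholded with a
block-wise Otsu criterion: the image is tiled into windows, a threshold is
computed per window, background-only windows inherit the median of their
neighbors, and the block-center thresholds are bilinearly interpolated to a
full-resolution threshold surface, which tolerates smooth illumination
gradients that defeat a single global threshold.

Phase-contrast images (dark cell bodies, bright halos, mid-gray
background) are instead segmented by iterative range filtering: cells are
*textured* regions, so the local intensity range (max - min in a small
window) is high over cells and near zero over background; thresholding the
range image and consolidating with binary closing, iterated a couple of
times, produces the foreground mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "otsu_threshold",
    "fluorescence_foreground",
    "phase_contrast_foreground",
]


def otsu_threshold(histogram: np.ndarray) -> int:
    """Threshold bin maximizing between-class variance.

    Pixels with value >= the returned bin index are foreground.  Ties are
    broken toward the lower index.  Raises on a single-valued histogram
    (no threshold separates one class).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if (hist > 0).sum() < 2:
        raise ValueError("histogram has fewer than 2 non-empty bins")
    total = hist.sum()
    bins = np.arange(hist.size, dtype=np.float64)
    # class 0 = bins < t, class 1 = bins >= t, for t = 1..size-1
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    m0 = np.cumsum(hist * bins)[:-1]
    mean_total = float((hist * bins).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mean_total - m0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    return int(np.argmax(between)) + 1


#: an Otsu split is treated as real (bimodal) only when the class-mean
#: separation exceeds this multiple of the pooled within-class spread;
#: a pure-noise Gaussian block splits at ~2.7, genuine cell/background
#: blocks at >10
BIMODALITY_RATIO = 4.0
#: minimum class-mean separation (bins of the 0-255 scale); rejects the
#: adjacent-bin splits of a nearly constant block
MIN_CONTRAST_BINS = 8.0


def _bimodal(hist: np.ndarray, t: int) -> bool:
    """Separation test for a proposed Otsu split of a block histogram."""
    bins = np.arange(hist.size, dtype=np.float64)
    w0, w1 = hist[:t].sum(), hist[t:].sum()
    if w0 == 0 or w1 == 0:
        return False
    mu0 = (hist[:t] * bins[:t]).sum() / w0
    mu1 = (hist[t:] * bins[t:]).sum() / w1
    var0 = (hist[:t] * (bins[:t] - mu0) ** 2).sum() / w0
    var1 = (hist[t:] * (bins[t:] - mu1) ** 2).sum() / w1
    total = w0 + w1
    within = np.sqrt((w0 * var0 + w1 * var1) / total)
    if mu1 - mu0 < MIN_CONTRAST_BINS:
        return False
    return mu1 - mu0 >= BIMODALITY_RATIO * max(within, 1e-12)


def _block_otsu_grid(
    img: np.ndarray, window: int, max_value: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block Otsu thresholds on a block grid; degenerate blocks get NaN."""
    h, w = img.shape
    n_r = max(h // window, 1)
    n_c = max(w // window, 1)
    centers_r = np.zeros(n_r)
    centers_c = np.zeros(n_c)
    thresholds = np.full((n_r, n_c), np.nan)
    scale = 255.0 / max_value if max_value > 0 else 1.0
    for i in range(n_r):
        r0 = i * window
        r1 = h if i == n_r - 1 else (i + 1) * window
        centers_r[i] = (r0 + r1 - 1) / 2.0
        for j in range(n_c):
            c0 = j * window
            c1 = w if j == n_c - 1 else (j + 1) * window
            centers_c[j] = (c0 + c1 - 1) / 2.0
            block = img[r0:r1, c0:c1]
            quant = np.clip((block * scale).astype(np.int64), 0, 255)
            hist = np.bincount(quant.ravel(), minlength=256).astype(np.float64)
            if (hist > 0).sum() < 2:
                continue
            t_bin = otsu_threshold(hist)
            if not _bimodal(hist, t_bin):
                continue  # background-only (unimodal) block
            thresholds[i, j] = (t_bin - 0.5) / scale
    return centers_r, centers_c, thresholds


def _fill_degenerate(thresholds: np.ndarray) -> np.ndarray:
    """Degenerate blocks inherit the median of defined neighbor thresholds."""
    out = thresholds.copy()
    if np.all(np.isnan(out)):
        raise ValueError("no block yielded a threshold; image may be uniform")
    while np.isnan(out).any():
        updated = out.copy()
        progress = False
        nan_r, nan_c = np.nonzero(np.isnan(out))
        for i, j in zip(nan_r, nan_c):
            neigh = out[
                max(i - 1, 0):i + 2, max(j - 1, 0):j + 2
            ]
            vals = neigh[np.isfinite(neigh)]
            if vals.size:
                updated[i, j] = np.median(vals)
                progress = True
        out = updated
        if not progress:  # disconnected NaN region: use global median
            out[np.isnan(out)] = np.nanmedian(out)
    return out


def _bilinear_surface(
    shape: tuple[int, int], centers_r: np.ndarray, centers_c: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Bilinear interpolation of block-center values to full resolution."""
    rows = np.arange(shape[0], dtype=np.float64)
    cols = np.arange(shape[1], dtype=np.float64)
    if centers_r.size == 1:
        row_interp = np.repeat(values, shape[0], axis=0)
    else:
        row_interp = np.empty((shape[0], values.shape[1]))
        for j in range(values.shape[1]):
            row_interp[:, j] = np.interp(rows, centers_r, values[:, j])
    if centers_c.size == 1:
        surface = np.repeat(row_interp, shape[1], axis=1)
    else:
        surface = np.empty(shape)
        for i in range(shape[0]):
            surface[i] = np.interp(cols, centers_c, row_interp[i])
    return surface


def _postprocess(mask: np.ndarray, min_object_area: int) -> np.ndarray:
    """Hole fill (4-connected background) and small-component removal."""
    structure = ndimage.generate_binary_structure(2, 1)
    filled = ndimage.binary_fill_holes(mask, structure=structure)
    if min_object_area > 1:
        labeled, n = ndimage.label(filled, structure=structure)
        if n:
            areas = np.bincount(labeled.ravel())
            small = np.flatnonzero(areas < min_object_area)
            filled[np.isin(labeled, small[small > 0])] = False
    return filled


def fluorescence_foreground(
    img: np.ndarray,
    window: int = 64,
    max_value: float | None = None,
    min_object_area: int = 1,
) -> np.ndarray:
    """Block-wise Otsu + bilinear interpolation foreground mask."""
    img = np.asarray(img, dtype=np.float64)
    if window < 16:
        raise ValueError("window must be >= 16")
    if window > min(img.shape):
        raise ValueError("window larger than the image")
    if max_value is None:
        max_value = float(img.max()) if img.max() > 0 else 1.0
    centers_r, centers_c, thresholds = _block_otsu_grid(img, window, max_value)
    if np.all(np.isnan(thresholds)):
        # every block is unimodal: nothing resembling foreground anywhere
        return np.zeros(img.shape, dtype=bool)
    thresholds = _fill_degenerate(thresholds)
    surface = _bilinear_surface(img.shape, centers_r, centers_c, thresholds)
    return _postprocess(img > surface, min_object_area)


def phase_contrast_foreground(
    img: np.ndarray,
    window: int = 5,
    n_iter: int = 2,
    closing_radius: int = 2,
    min_object_area: int = 1,
) -> np.ndarray:
    """Iterative range filtering foreground mask for phase contrast."""
    img = np.asarray(img, dtype=np.float64)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    size = (window, window)
    rng_img = ndimage.maximum_filter(img, size=size) - ndimage.minimum_filter(img, size=size)
    if rng_img.max() <= 0:
        return np.zeros(img.shape, dtype=bool)
    current = rng_img
    mask = np.zeros(img.shape, dtype=bool)
    structure = ndimage.generate_binary_structure(2, 2)
    for _ in range(n_iter):
        quant = np.clip((current / current.max() * 255.0).astype(np.int64), 0, 255)
        hist = np.bincount(quant.ravel(), minlength=256)
        if (hist > 0).sum() < 2:
            break
        t = (otsu_threshold(hist) - 0.5) / 255.0 * current.max()
        mask = current > t
        mask = ndimage.binary_closing(mask, structure=structure, iterations=closing_radius)
        # consolidation: the next pass thresholds the local density of the
        # current mask, filling textured cell regions and dropping specks
        current = ndimage.uniform_filter(mask.astype(np.float64), size=window)
    return _postprocess(mask, min_object_area)
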