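"""Recursive threshold decomposition of the fuzzy edge image.

The fuzzy edge image is binarized starting from its strongest level:
pixels whose vote count reaches the current threshold are treated as edges
and removed, and the remaining pixels are labeled into connected
components.  Any component still larger than the maximum plausible cell
area is re-decomposed with the threshold lowered by one, restricted to
that component, until the threshold reaches a configured lower bound.
This adapts the effective edge threshold per object: isolated cells
separate at strong edges only, while dense clumps recurse to weaker edges.

Removed edge pixels are finally re-assigned to the geodesically nearest
accepted component (iterative 4/8-neighbor dilation inside the region of
interest, ties to the lower label id) so that objects are contiguous, and
components below the small-object floor are discarded.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["binary_threshold", "threshold_decompose"]


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def binary_threshold(votes: np.ndarray, i: int) -> np.ndarray:
    """Level-``i`` binary slice of the fuzzy edge image: ``votes >= i``."""
    return np.asarray(votes) >= i


def _decompose(
    votes: np.ndarray,
    region: np.ndarray,
    f: int,
    f_min: int,
    max_area: int,
    structure: np.ndarray,
    out: np.ndarray,
    next_label: int,
) -> int:
    """Recursive worker; paints accepted components into ``out``.

    Returns the next free label id.  ``region`` is the pixel set being
    decomposed; pixels with votes >= f are removed before labeling.
    """
    keep = region & ~binary_threshold(votes, f)
    labeled, n = ndimage.label(keep, structure=structure)
    if n == 0:
        return next_label
    areas = np.bincount(labeled.ravel())[1:]
    slices = ndimage.find_objects(labeled)
    for idx in range(n):
        sl = slices[idx]
        comp = labeled[sl] == idx + 1
        if areas[idx] > max_area and f - 1 >= f_min:
            sub_region = np.zeros(votes.shape, dtype=bool)
            sub_region[sl] = comp
            next_label = _decompose(
                votes, sub_region, f - 1, f_min, max_area, structure, out, next_label
            )
        else:
            out[sl][comp] = next_label
            next_label += 1
    return next_label


def _assign_edge_pixels(
    labels: np.ndarray, roi: np.ndarray, connectivity: int
) -> np.ndarray:
    """Geodesic nearest-label assignment of unlabeled roi pixels.

    Iteratively propagates labels to adjacent unassigned pixels inside the
    roi; when several labels reach a pixel in the same round the lowest id
    wins.  Pixels unreachable from any label (isolated edge islands) stay 0.
    """
    out = labels.copy()
    sentinel = np.iinfo(out.dtype).max
    if connectivity == 4:
        steps = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    pending = roi & (out == 0)
    while pending.any():
        cand = np.full(out.shape, sentinel, dtype=out.dtype)
        filled = np.where(out > 0, out, sentinel)
        for dr, dc in steps:
            shifted = np.full(out.shape, sentinel, dtype=out.dtype)
            rows, cols = out.shape
            shifted[max(0, dr):rows + min(0, dr), max(0, dc):cols + min(0, dc)] = filled[
                max(0, -dr):rows + min(0, -dr), max(0, -dc):cols + min(0, -dc)
            ]
            np.minimum(cand, shifted, out=cand)
        grow = pending & (cand < sentinel)
        if not grow.any():
            break  # unreachable pixels remain background
        out[grow] = cand[grow]
        pending &= ~grow
    return out


def threshold_decompose(
    votes: np.ndarray,
    roi: np.ndarray,
    f: int,
    f_min: int,
    max_cell_area: int,
    min_object_area: int = 1,
    connectivity: int = 4,
) -> np.ndarray:
    """Decompose the region of interest into labeled objects.

    Parameters
    ----------
    votes:
        Fuzzy edge image (integer votes in ``[0, S]``).
    roi:
        Foreground mask restricting the decomposition.
    f:
        Starting (strongest) edge threshold, normally ``S``.
    f_min:
        Lower bound of the decomposition; components still oversized at
        ``f_min`` are accepted as-is and left to the split stage.
    max_cell_area:
        Area above which a component is decomposed further.
    min_object_area:
        Components below this area are discarded after edge-pixel
        re-assignment.
    """
    votes = np.asarray(votes)
    roi = np.asarray(roi, dtype=bool)
    if not (1 <= f_min <= f):
        raise ValueError("need 1 <= f_min <= f")
    out = np.zeros(votes.shape, dtype=np.int32)
    if not roi.any():
        return out
    structure = _structure(connectivity)
    # decomposition subdivides only oversized objects: foreground
    # components already within the size bound are accepted whole
    labeled, n = ndimage.label(roi, structure=structure)
    areas = np.bincount(labeled.ravel())[1:]
    slices = ndimage.find_objects(labeled)
    next_label = 1
    for idx in range(n):
        sl = slices[idx]
        comp = labeled[sl] == idx + 1
        if areas[idx] > max_cell_area:
            region = np.zeros(votes.shape, dtype=bool)
            region[sl] = comp
            next_label = _decompose(
                votes, region, f, f_min, max_cell_area, structure, out, next_label
            )
        else:
            out[sl][comp] = next_label
            next_label += 1
    out = _assign_edge_pixels(out, roi, connectivity)
    if min_object_area > 1:
        areas = np.bincount(out.ravel())
        small = np.flatnonzero(areas < min_object_area)
        out[np.isin(out, small[small > 0])] = 0
    return _relabel_consecutive(out)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map positive labels onto 1..n preserving order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    lut[present] = np.arange(1, present.size + 1, dtype=labels.dtype)
    return lut[labels]
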