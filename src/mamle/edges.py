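"""Multi-scale morphological edge detection.

An edge pixel is a directional local intensity minimum: at scale ``s`` and
direction ``d`` the detector probes the two pixels at distance ``s`` along
``d`` (horizontal, vertical, and the two diagonals) and marks the pixel if
neither probe is darker.  Per-scale edges are the union over the four
directions; summing the per-scale binary edges over scales ``1..S`` yields
the *fuzzy edge image*, an integer vote map in ``[0, S]`` where strong,
scale-persistent valleys (the dark boundaries between touching cells) score
close to ``S`` and textured interiors score low.

Images are quantized to their source integer range before detection:
comparing a pixel against a grayscale erosion is an equality test, which is
only well-posed on integer-valued rasters.

Borders are padded with +inf (the neutral element of the minimum), so border
pixels compare only against their in-image neighbors.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["StructElem", "structuring_element", "directional_edge", "fuzzy_edge_image"]

# (row, col) unit steps for directions 1..4:
# 1 horizontal, 2 vertical, 3 main diagonal, 4 anti-diagonal
_DIRECTION_STEPS = {1: (0, 1), 2: (1, 0), 3: (1, 1), 4: (1, -1)}


@dataclasses.dataclass(frozen=True)
class StructElem:
    """Two-point directional probe at distance ``s`` from the origin.

    ``support`` is a (2s+1)x(2s+1) binary matrix (1x(2s+1) for horizontal,
    (2s+1)x1 for vertical) with ones only at the two endpoints; the origin
    cell at the center is *not* part of the support.
    """

    support: np.ndarray
    origin: tuple[int, int]
    scale: int
    direction: int

    @property
    def offsets(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """The two probed offsets relative to the origin."""
        dr, dc = _DIRECTION_STEPS[self.direction]
        s = self.scale
        return (-s * dr, -s * dc), (s * dr, s * dc)


def structuring_element(s: int, d: int) -> StructElem:
    """Build the scale-``s`` direction-``d`` probe element."""
    if s < 1:
        raise ValueError("scale must be >= 1")
    if d not in _DIRECTION_STEPS:
        raise ValueError("direction must be in 1..4")
    if d == 1:
        support = np.zeros((1, 2 * s + 1), dtype=bool)
        support[0, 0] = support[0, -1] = True
        origin = (0, s)
    elif d == 2:
        support = np.zeros((2 * s + 1, 1), dtype=bool)
        support[0, 0] = support[-1, 0] = True
        origin = (s, 0)
    else:
        support = np.zeros((2 * s + 1, 2 * s + 1), dtype=bool)
        if d == 3:
            support[0, 0] = support[-1, -1] = True
        else:
            support[0, -1] = support[-1, 0] = True
        origin = (s, s)
    return StructElem(support=support, origin=origin, scale=s, direction=d)


def _shifted(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """View of ``img`` shifted by (dr, dc), padded with +inf outside."""
    out = np.full(img.shape, np.inf)
    rows, cols = img.shape
    src_r = slice(max(0, -dr), min(rows, rows - dr))
    src_c = slice(max(0, -dc), min(cols, cols - dc))
    dst_r = slice(max(0, dr), min(rows, rows + dr))
    dst_c = slice(max(0, dc), min(cols, cols + dc))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def directional_edge(img: np.ndarray, s: int, d: int) -> np.ndarray:
    """Binary edge mask at scale ``s``, direction ``d``.

    A pixel is marked iff it is unchanged by the grayscale erosion with the
    two-point probe, i.e. iff it is not brighter than either probed
    neighbor.
    """
    elem = structuring_element(s, d)
    img = np.asarray(img, dtype=np.float64)
    (r1, c1), (r2, c2) = elem.offsets
    eroded = np.minimum(_shifted(img, -r1, -c1), _shifted(img, -r2, -c2))
    return img <= eroded


def fuzzy_edge_image(
    img: np.ndarray, max_scale: int, roi: np.ndarray | None = None
) -> np.ndarray:
    """Accumulate directional-minimum votes over scales ``1..max_scale``.

    Per scale the four directional edge masks are OR-ed; the per-scale
    results are summed.  Pixels outside ``roi`` are forced to zero.
    Returns an integer array with values in ``[0, max_scale]``.
    """
    if max_scale < 1:
        raise ValueError("max_scale must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    votes = np.zeros(img.shape, dtype=np.int32)
    for s in range(1, max_scale + 1):
        scale_edge = np.zeros(img.shape, dtype=bool)
        for d in (1, 2, 3, 4):
            scale_edge |= directional_edge(img, s, d)
        votes += scale_edge
    if roi is not None:
        votes[~np.asarray(roi, dtype=bool)] = 0
    return votes
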