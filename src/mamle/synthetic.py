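"""Synthetic microscopy images of dense microbial colonies.

Generates fluorescence-like (bright cells, dark background) and
phase-contrast-like (dark bodies, bright halos) images of rod-shaped
(E. coli-like spherocylinders) or round (S. aureus-like disks) cells in
dense clumps, paired with ground-truth label masks.  The generator
controls the properties that make dense-colony segmentation hard:

* ``clumping`` — fraction of cells placed touching an already-placed cell,
  separated only by a 1-2 px background-level valley (the boundary cue the
  edge detector must find);
* ``fusion_rate`` — fraction of touching placements rendered with *no*
  valley at all, a deliberate under-segmentation challenge whose pairs are
  listed in the metadata;
* ``snr`` — foreground contrast divided by the additive noise standard
  deviation (shot noise is added on top, at a fixed camera gain);
* ``illumination_gradient`` — relative amplitude of a linear shading ramp;
* ``psf_sigma`` — Gaussian blur emulating the point-spread function.

All randomness flows from ``params.seed``; identical parameters give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import GrayImage

__all__ = ["ColonyParams", "generate_colony", "generate_phase_contrast", "PRESETS", "preset"]

#: rendered foreground-background contrast, 8-bit units
CONTRAST = 120.0
#: background level, 8-bit units
BACKGROUND = 30.0
#: camera gain (DN per photon^-1): shot-noise variance = intensity / gain
CAMERA_GAIN = 20.0
#: relative amplitude of the smooth interior texture field
TEXTURE_AMPLITUDE = 0.06
_MAX_TRIES = 300


@dataclasses.dataclass(frozen=True)
class ColonyParams:
    """Geometry and rendering parameters of one synthetic colony image."""

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 200
    cell_shape: str = "rod"  # "rod" or "coccus"
    length_range: tuple[float, float] = (20.0, 40.0)
    width_range: tuple[float, float] = (7.0, 11.0)
    clumping: float = 0.7
    fusion_rate: float = 0.0
    snr: float = 5.0
    illumination_gradient: float = 0.0
    psf_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.clumping <= 1.0 and 0.0 <= self.fusion_rate <= 1.0):
            raise ValueError("clumping and fusion_rate must be in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.cell_shape not in ("rod", "coccus"):
            raise ValueError("cell_shape must be 'rod' or 'coccus'")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


#: named density conditions for a 512x512 field of view
PRESETS: dict[str, dict] = {
    "dense": {"n_cells": 200, "clumping": 0.7},
    "medium": {"n_cells": 100, "clumping": 0.5},
    "sparse": {"n_cells": 25, "clumping": 0.1},
}


def preset(name: str, **overrides) -> ColonyParams:
    """A named density preset (``dense``, ``medium``, ``sparse``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ColonyParams(**kwargs)


def _cell_mask(length: float, width: float, theta: float, shape: str) -> np.ndarray:
    """Rasterize one cell (spherocylinder or disk) into a tight crop."""
    radius = width / 2.0
    half = (length - width) / 2.0 if shape == "rod" else 0.0
    half = max(half, 0.0)
    ext = int(np.ceil(length / 2.0)) + 2
    yy, xx = np.mgrid[-ext:ext + 1, -ext:ext + 1].astype(np.float64)
    # axis direction
    ax_r, ax_c = np.sin(theta), np.cos(theta)
    t = yy * ax_r + xx * ax_c  # coordinate along the axis
    t_clamped = np.clip(t, -half, half)
    dr = yy - t_clamped * ax_r
    dc = xx - t_clamped * ax_c
    return dr * dr + dc * dc <= radius * radius


def _place_cells(params: ColonyParams, rng: np.random.Generator):
    """Rejection-sampling placement; returns (labels, cells, fused_pairs)."""
    h, w = params.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    dilated = np.zeros((h, w), dtype=bool)  # occupied grown by 1 px (8-conn)
    structure = ndimage.generate_binary_structure(2, 2)
    cells: list[dict] = []
    fused_pairs: list[tuple[int, int]] = []
    cell_pixels: list[tuple[np.ndarray, np.ndarray]] = []

    for i in range(params.n_cells):
        label = i + 1
        placed = False
        clumped = bool(i > 0 and rng.random() < params.clumping)
        fused = bool(clumped and rng.random() < params.fusion_rate)
        for attempt in range(_MAX_TRIES):
            if clumped and attempt == _MAX_TRIES // 2:
                # deeply buried partners can be unreachable; fall back to
                # free placement rather than failing the whole image
                clumped = fused = False
            length = rng.uniform(*params.length_range)
            width = rng.uniform(*params.width_range)
            if params.cell_shape == "coccus":
                length = width
            theta = rng.uniform(0.0, np.pi)
            if clumped:
                partner = int(rng.integers(1, label))
                p = cells[partner - 1]
                # rods in dense colonies pack locally aligned
                if params.cell_shape == "rod" and rng.random() < 0.7:
                    theta = (p["theta"] + rng.normal(0.0, 0.35)) % np.pi
                phi = rng.uniform(0.0, 2.0 * np.pi)
                # support-function distance at which the two capsules touch
                # along direction phi, plus the valley gap (none when fused)
                half_p = max(p["length"] - p["width"], 0.0) / 2.0
                half_n = max(length - width, 0.0) / 2.0
                h_p = half_p * abs(np.cos(phi - p["theta"])) + p["width"] / 2.0
                h_n = half_n * abs(np.cos(phi - theta)) + width / 2.0
                gap = rng.uniform(-0.8, 0.2) if fused else rng.uniform(1.6, 3.0)
                dist = h_p + h_n + gap
                cy = p["center"][0] + dist * np.sin(phi)
                cx = p["center"][1] + dist * np.cos(phi)
            else:
                partner = 0
                margin = length / 2.0 + 2.0
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
            crop = _cell_mask(length, width, theta, params.cell_shape)
            ext = crop.shape[0] // 2
            r0, c0 = int(round(cy)) - ext, int(round(cx)) - ext
            r1, c1 = r0 + crop.shape[0], c0 + crop.shape[1]
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                continue
            sub_occ = occupied[r0:r1, c0:c1]
            sub_dil = dilated[r0:r1, c0:c1]
            if fused:
                # trim to unoccupied space: the fused pair shares a border
                # with no background valley; slight overlap goes to the
                # earlier cell so ground-truth labels stay disjoint
                trimmed = crop & ~sub_occ
                if trimmed.sum() < 0.85 * crop.sum():
                    continue
                n_comp = ndimage.label(trimmed, structure=structure)[1]
                if n_comp != 1:
                    continue
                if not (
                    ndimage.binary_dilation(trimmed, structure=structure)
                    & (labels[r0:r1, c0:c1] == partner)
                ).any():
                    continue
                crop = trimmed
            else:
                if (crop & sub_dil).any():
                    continue
                if clumped:
                    reach = ndimage.binary_dilation(crop, structure=structure, iterations=2)
                    if not (reach & (labels[r0:r1, c0:c1] == partner)).any():
                        continue
            labels[r0:r1, c0:c1][crop] = label
            occupied[r0:r1, c0:c1][crop] = True
            dilated[r0:r1, c0:c1] |= ndimage.binary_dilation(crop, structure=structure)
            rr, cc = np.nonzero(crop)
            cell_pixels.append((rr + r0, cc + c0))
            cells.append(
                {
                    "label": label,
                    "center": (float(cy), float(cx)),
                    "length": float(length),
                    "width": float(width),
                    "theta": float(theta),
                    "fused_with": partner if fused else 0,
                }
            )
            if fused:
                fused_pairs.append((partner, label))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {label} of {params.n_cells} after "
                f"{_MAX_TRIES} attempts; lower the density (n_cells/clumping)"
            )
    return labels, cells, fused_pairs


def _render_fluorescence(
    labels: np.ndarray, cells: list[dict], params: ColonyParams, rng: np.random.Generator
) -> np.ndarray:
    h, w = labels.shape
    img = np.full((h, w), BACKGROUND, dtype=np.float64)
    fg = labels > 0
    if fg.any():
        # dome-like interior profile from the distance to the cell border,
        # normalized by each cell's width
        edt = ndimage.distance_transform_edt(fg)
        widths = np.array([1.0] + [c["width"] for c in cells])
        norm = widths[labels] / 3.0
        profile = 0.7 + 0.3 * np.minimum(edt / np.maximum(norm, 1e-9), 1.0)
        texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.5)
        texture /= max(texture.std(), 1e-9)
        img[fg] = BACKGROUND + CONTRAST * profile[fg] * (1.0 + TEXTURE_AMPLITUDE * texture[fg])
    if params.illumination_gradient:
        ramp = np.linspace(-0.5, 0.5, w)[None, :] * params.illumination_gradient * CONTRAST
        img = img + ramp
    img = ndimage.gaussian_filter(img, params.psf_sigma)
    sigma_read = CONTRAST / params.snr
    shot = rng.standard_normal((h, w)) * np.sqrt(np.maximum(img, 0.0) / CAMERA_GAIN)
    read = rng.standard_normal((h, w)) * sigma_read
    img = img + shot + read
    return np.clip(np.rint(img), 0, 255).astype(np.float64)


def generate_colony(params: ColonyParams):
    """Fluorescence-like colony image with ground truth.

    Returns ``(GrayImage, label_mask, metadata)`` where metadata lists the
    per-cell geometry, the fused pairs (rendered without a boundary
    valley), and the dividing-cell labels (none by default).
    """
    rng = np.random.default_rng(params.seed)
    labels, cells, fused_pairs = _place_cells(params, rng)
    img = _render_fluorescence(labels, cells, params, rng)
    metadata = {
        "cells": cells,
        "fused_pairs": fused_pairs,
        "dividing": [],
        "params": dataclasses.asdict(params),
    }
    return GrayImage(img, bit_depth=8), labels, metadata


def generate_phase_contrast(params: ColonyParams):
    """Phase-contrast-like colony image: dark bodies, bright halos."""
    rng = np.random.default_rng(params.seed)
    labels, cells, fused_pairs = _place_cells(params, rng)
    h, w = labels.shape
    mid = 128.0
    body_drop = 60.0
    halo_rise = 45.0
    img = np.full((h, w), mid, dtype=np.float64)
    fg = labels > 0
    halo = ndimage.binary_dilation(fg, ndimage.generate_binary_structure(2, 2), iterations=2) & ~fg
    img[fg] = mid - body_drop
    img[halo] = mid + halo_rise
    if params.illumination_gradient:
        img += np.linspace(-0.5, 0.5, w)[None, :] * params.illumination_gradient * body_drop
    img = ndimage.gaussian_filter(img, params.psf_sigma)
    img += rng.standard_normal((h, w)) * (body_drop / params.snr)
    img = np.clip(np.rint(img), 0, 255).astype(np.float64)
    metadata = {
        "cells": cells,
        "fused_pairs": fused_pairs,
        "dividing": [],
        "params": dataclasses.asdict(params),
    }
    return GrayImage(img, bit_depth=8), labels, metadata
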