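"""End-to-end segmentation pipeline.

Runs the seven stages in order: collaborative denoising, modality-specific
foreground extraction, multi-scale morphological edge detection, recursive
threshold decomposition (initial segmentation), Gaussian shape-model
learning, likelihood-maximizing splitting, and maximum-likelihood merging,
followed by a small-object filter.  Per-stage object counts are returned
as diagnostics.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .config import PipelineConfig
from .denoise import DenoiseParams, denoise, estimate_noise_sigma
from .edges import fuzzy_edge_image
from .foreground import fluorescence_foreground, phase_contrast_foreground
from .io import GrayImage
from .decompose import threshold_decompose, _relabel_consecutive
from .shape import ShapeModel, all_region_features, fit_shape_model
from .split_merge import merge_fragments, recursive_split

__all__ = ["StageDiagnostics", "segment"]


@dataclasses.dataclass
class StageDiagnostics:
    """Object counts after each stage, plus optional stage masks."""

    n_initial: int = 0
    n_after_split: int = 0
    n_after_merge: int = 0
    n_final: int = 0
    foreground_fraction: float = 0.0
    noise_sigma: float = 0.0
    warnings: list[str] = dataclasses.field(default_factory=list)
    stage_masks: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)


def segment(
    img: GrayImage | np.ndarray,
    config: PipelineConfig | None = None,
    denoiser: Callable[..., np.ndarray] | None = None,
    denoise_sigma: float | None = None,
    do_split: bool = True,
    do_merge: bool = True,
    refit_after_split: bool = False,
    keep_stage_masks: bool = False,
) -> tuple[np.ndarray, ShapeModel | None, StageDiagnostics]:
    """Segment one grayscale image into labeled cells.

    Parameters
    ----------
    img:
        Input image (``GrayImage`` or 2-D array, treated as 8-bit scale).
    config:
        Pipeline settings; defaults are tuned for 512x512 fluorescence
        images of rod-shaped cells.
    denoiser:
        Drop-in replacement for the built-in collaborative filter, called
        as ``denoiser(pixels, params, value_range)``; pass a lambda
        returning its input to disable denoising.
    denoise_sigma:
        Noise standard deviation; estimated from the image when ``None``.
    do_split / do_merge:
        Ablation switches for the two correction passes.
    refit_after_split:
        Refit the shape model on the post-split population before merging.

    Returns ``(label_mask, shape_model, diagnostics)``; the shape model is
    ``None`` when the foreground is empty.
    """
    if isinstance(img, GrayImage):
        pixels = img.pixels
        max_value = float(img.max_value)
    else:
        pixels = np.asarray(img, dtype=np.float64)
        max_value = 255.0
    config = config or PipelineConfig()
    diag = StageDiagnostics()

    # i) denoise
    fn = denoiser or denoise
    params = DenoiseParams(sigma=denoise_sigma)
    clean = fn(pixels, params, (0.0, max_value))
    diag.noise_sigma = (
        denoise_sigma if denoise_sigma is not None else float(estimate_noise_sigma(pixels))
    )
    # quantize back to the source integer range: the edge detector's
    # erosion-invariance test is defined on integer rasters
    quant = np.rint(clean)

    # ii) foreground
    if config.modality == "fluorescence":
        roi = fluorescence_foreground(
            quant,
            window=config.threshold_window,
            max_value=max_value,
            min_object_area=config.min_object_area,
        )
        edge_input = quant
    else:
        roi = phase_contrast_foreground(quant, min_object_area=config.min_object_area)
        edge_input = max_value - quant  # boundaries must be intensity minima
    diag.foreground_fraction = float(roi.mean())
    empty = np.zeros(pixels.shape, dtype=np.int32)
    if not roi.any():
        diag.warnings.append("empty foreground mask; no cells detected")
        return empty, None, diag

    # iii) multi-scale edges, iv) threshold decomposition
    votes = fuzzy_edge_image(edge_input, config.max_scale, roi)
    initial = threshold_decompose(
        votes,
        roi,
        f=config.max_scale,
        f_min=config.decomposition_bound,
        max_cell_area=config.max_cell_area,
        min_object_area=config.min_object_area,
        connectivity=config.connectivity,
    )
    diag.n_initial = int(initial.max())
    if keep_stage_masks:
        diag.stage_masks["initial"] = initial.copy()

    # v) shape learning
    feats = all_region_features(initial)
    try:
        model = fit_shape_model(
            list(feats.values()),
            max_cell_area=config.max_cell_area,
            min_object_area=config.min_object_area,
        )
    except ValueError as exc:
        diag.warnings.append(f"shape model not fitted: {exc}")
        return initial, None, diag

    # vi) likelihood split
    mask = initial
    if do_split:
        mask = recursive_split(mask, model, config.max_cell_area, config.connectivity)
    diag.n_after_split = int(mask.max())
    if keep_stage_masks:
        diag.stage_masks["split"] = mask.copy()

    # vii) maximum-likelihood merge
    if do_merge:
        merge_model = model
        if refit_after_split:
            try:
                merge_model = fit_shape_model(
                    list(all_region_features(mask).values()),
                    max_cell_area=config.max_cell_area,
                    min_object_area=config.min_object_area,
                )
            except ValueError:
                pass
        mask = merge_fragments(mask, merge_model)
    diag.n_after_merge = int(mask.max())

    # final small-object filter
    areas = np.bincount(mask.ravel())
    small = np.flatnonzero(areas < config.min_object_area)
    if small.size:
        mask = mask.copy()
        mask[np.isin(mask, small[small > 0])] = 0
        mask = _relabel_consecutive(mask)
    diag.n_final = int(mask.max())
    if keep_stage_masks:
        diag.stage_masks["final"] = mask.copy()
    return mask, model, diag
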