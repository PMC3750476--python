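"""Segmentation scoring against ground truth.

Every ground-truth cell falls in exactly one of four classes:

* **TP** — exactly one predicted object majority-overlaps the cell (> 50 %
  of the cell's pixels) and that object's own pixel majority lies in the
  cell (a clean one-to-one match);
* **over-segmented** — at least two predicted objects each take >= 20 % of
  the cell's pixels;
* **under-segmented** — the cell's majority predictor also majority-covers
  another cell (several cells recognized as one object);
* **FN** — no predicted object covers >= 50 % of the cell.

Predicted objects with less than half their pixels on any cell are false
positives; they are counted but excluded from the accuracy, which is
``100 * TP / n_cells``.  Cells flagged as dividing are excluded from all
counts (a dividing cell is legitimately either one or two objects).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np

__all__ = ["EvalReport", "classify_detections", "parameter_sweep", "grid_sweep"]


def _predenoised(images: Sequence) -> list:
    """Denoise each image once; sweeps vary only post-denoise parameters."""
    from .denoise import DenoiseParams, denoise
    from .io import GrayImage

    cached = []
    for img in images:
        pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
        max_value = float(img.max_value) if isinstance(img, GrayImage) else 255.0
        clean = denoise(pixels, DenoiseParams(), (0.0, max_value))
        cached.append(lambda _px, _pp, _vr, _c=clean: _c)
    return cached

MAJORITY = 0.5
FRAGMENT_FLOOR = 0.2


@dataclasses.dataclass
class EvalReport:
    """Counts and per-cell assignments of the four-class evaluation."""

    n_cells: int
    TP: int
    over_seg: int
    under_seg: int
    FN: int
    FP: int
    n_detections: int
    per_cell: dict[int, str]

    @property
    def accuracy(self) -> float:
        """Segmentation accuracy, percent: 100 * TP / n_cells."""
        return 100.0 * self.TP / self.n_cells if self.n_cells else 0.0

    @property
    def fp_rate(self) -> float:
        """False positives as a percentage of all detections."""
        return 100.0 * self.FP / self.n_detections if self.n_detections else 0.0

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "TP": self.TP,
            "over_seg": self.over_seg,
            "under_seg": self.under_seg,
            "FN": self.FN,
            "FP": self.FP,
            "n_detections": self.n_detections,
            "accuracy": self.accuracy,
            "fp_rate": self.fp_rate,
        }


def classify_detections(
    gt: np.ndarray, pred: np.ndarray, dividing: Iterable[int] = ()
) -> EvalReport:
    """Score a predicted label mask against a ground-truth label mask."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction must have the same shape")
    dividing = set(int(d) for d in dividing)
    n_gt = int(gt.max())
    n_pred = int(pred.max())
    # contingency table: overlap[g, p] = pixels with gt==g and pred==p
    pair = gt.astype(np.int64) * (n_pred + 1) + pred.astype(np.int64)
    counts = np.bincount(pair.ravel(), minlength=(n_gt + 1) * (n_pred + 1))
    overlap = counts.reshape(n_gt + 1, n_pred + 1)
    gt_sizes = overlap.sum(axis=1)
    pred_sizes = overlap.sum(axis=0)

    # majority predictor of each gt cell, and vice versa
    per_cell: dict[int, str] = {}
    tp = over = under = fn = 0
    pred_majority_cell = np.zeros(n_pred + 1, dtype=np.int64)
    for p in range(1, n_pred + 1):
        if pred_sizes[p] == 0:
            continue
        g_best = int(np.argmax(overlap[1:, p])) + 1 if n_gt else 0
        if n_gt and overlap[g_best, p] > MAJORITY * pred_sizes[p]:
            pred_majority_cell[p] = g_best
    # how many gt cells each predictor majority-covers (for under-seg)
    covers: dict[int, int] = {}
    majority_pred = np.zeros(n_gt + 1, dtype=np.int64)
    for g in range(1, n_gt + 1):
        if gt_sizes[g] == 0:
            continue
        p_best = int(np.argmax(overlap[g, 1:])) + 1 if n_pred else 0
        if n_pred and overlap[g, p_best] > MAJORITY * gt_sizes[g]:
            majority_pred[g] = p_best
            covers[p_best] = covers.get(p_best, 0) + 1

    for g in range(1, n_gt + 1):
        if gt_sizes[g] == 0:
            continue
        if g in dividing:
            per_cell[g] = "dividing"
            continue
        fragments = int((overlap[g, 1:] >= FRAGMENT_FLOOR * gt_sizes[g]).sum())
        p = majority_pred[g]
        if p == 0:
            if fragments >= 2:
                per_cell[g] = "over_seg"
                over += 1
            else:
                per_cell[g] = "FN"
                fn += 1
        elif covers.get(p, 0) >= 2:
            per_cell[g] = "under_seg"
            under += 1
        elif fragments >= 2:
            per_cell[g] = "over_seg"
            over += 1
        elif pred_majority_cell[p] == g:
            per_cell[g] = "TP"
            tp += 1
        else:
            per_cell[g] = "FN"
            fn += 1

    fp = 0
    for p in range(1, n_pred + 1):
        if pred_sizes[p] == 0:
            continue
        on_cells = overlap[1:, p].sum()
        if on_cells < MAJORITY * pred_sizes[p]:
            fp += 1
    n_detections = int((pred_sizes[1:] > 0).sum())
    n_cells = int((gt_sizes[1:] > 0).sum()) - len(
        [d for d in dividing if 0 < d <= n_gt and gt_sizes[d] > 0]
    )
    return EvalReport(
        n_cells=n_cells,
        TP=tp,
        over_seg=over,
        under_seg=under,
        FN=fn,
        FP=fp,
        n_detections=n_detections,
        per_cell=per_cell,
    )


def parameter_sweep(
    images: Sequence,
    config,
    param: str,
    values: Sequence,
) -> dict:
    """Run the full pipeline across values of one parameter.

    ``images`` is a sequence of ``GrayImage`` (or 2-D arrays).  Returns the
    detected-cell counts per value plus the coefficients of variation of
    the counts and of the parameter values.  Infeasible combinations
    (e.g. a decomposition bound above the scale count) are skipped.
    """
    from .pipeline import segment  # deferred: pipeline imports this module's report

    allowed = {"max_cell_area", "max_scale", "decomposition_bound"}
    if param not in allowed:
        raise ValueError(f"param must be one of {sorted(allowed)}")
    denoisers = _predenoised(images)
    counts: list[int] = []
    used_values: list[float] = []
    for value in values:
        try:
            cfg = config.replace(**{param: int(value)})
        except ValueError as exc:
            logging.getLogger(__name__).warning("skipping %s=%s: %s", param, value, exc)
            continue
        total = 0
        for img, dn in zip(images, denoisers):
            mask, _model, _diag = segment(img, cfg, denoiser=dn)
            total += int(mask.max())
        counts.append(total)
        used_values.append(float(value))
    counts_arr = np.asarray(counts, dtype=np.float64)
    vals_arr = np.asarray(used_values, dtype=np.float64)

    def cv(a: np.ndarray) -> float:
        return float(a.std() / a.mean()) if a.size and a.mean() else 0.0

    return {
        "param": param,
        "values": used_values,
        "counts": counts,
        "cv_counts": cv(counts_arr),
        "cv_values": cv(vals_arr),
    }


def grid_sweep(
    images: Sequence,
    config,
    scales: Sequence[int],
    bounds: Sequence[int],
) -> dict:
    """Detected-cell counts over the (max_scale, decomposition_bound) grid.

    Infeasible pairs (bound above the scale count) are recorded as NaN.
    Returns the count grid plus the fraction of feasible cells whose count
    lies within 10% of the modal (most common bin) count, restricted to
    the largest connected region of such cells.
    """
    from .pipeline import segment

    denoisers = _predenoised(images)
    grid = np.full((len(scales), len(bounds)), np.nan)
    for a, s in enumerate(scales):
        for b, f in enumerate(bounds):
            if f > s:
                continue
            cfg = config.replace(max_scale=int(s), decomposition_bound=int(f))
            total = 0
            for img, dn in zip(images, denoisers):
                mask, _model, _diag = segment(img, cfg, denoiser=dn)
                total += int(mask.max())
            grid[a, b] = total
    feasible = np.isfinite(grid)
    counts = grid[feasible]
    # modal count: the most populated 10%-wide band
    order = np.sort(counts)
    best_center, best_hits = order[0], 0
    for center in order:
        hits = int(np.sum(np.abs(counts - center) <= 0.1 * center))
        if hits > best_hits:
            best_center, best_hits = center, hits
    stable = feasible & (np.abs(grid - best_center) <= 0.1 * best_center)
    # largest 4-connected region of stable cells
    from scipy import ndimage

    lab, n = ndimage.label(stable)
    region = 0
    if n:
        region = int(np.bincount(lab.ravel())[1:].max())
    return {
        "scales": list(scales),
        "bounds": list(bounds),
        "counts": grid.tolist(),
        "modal_count": float(best_center),
        "stable_fraction": region / int(feasible.sum()) if feasible.sum() else 0.0,
        "n_feasible": int(feasible.sum()),
    }
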