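"""Cell-shape model: features, Gaussian fit, and Mahalanobis scoring.

Each segmented object is summarized by three morphological features --
area, major-axis length, minor-axis length -- where the axes are those of
the *equivalent ellipse*, the ellipse with the same normalized second
central moments as the pixel set (axis length = 4*sqrt(eigenvalue)).  The
population of objects in a correct segmentation is modeled as a single
multivariate Gaussian N(mu, Sigma) in this 3-D feature space, estimated
robustly from the initial segmentation; the (squared) Mahalanobis distance

    D(x) = (x - mu)^T Sigma^{-1} (x - mu)

is the covariance-normalized misfit of an object to the learned cell
shape.  For a fixed Sigma the Gaussian log-likelihood is a decreasing
affine function of D, so minimizing D maximizes likelihood; the split and
merge stages use D directly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "FeatureVector",
    "ShapeModel",
    "region_features",
    "features_of_coords",
    "all_region_features",
    "fit_shape_model",
    "mahalanobis_D",
    "log_likelihood",
]

MIN_REGION_PIXELS = 5
MIN_FIT_OBJECTS = 10
#: relative ridge added to Sigma's diagonal so it is always invertible
RIDGE_FRACTION = 1e-6


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """(area, major axis, minor axis) of one object, in pixel units."""

    area: float
    major: float
    minor: float

    def as_array(self) -> np.ndarray:
        return np.array([self.area, self.major, self.minor], dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class ShapeModel:
    """Multivariate Gaussian over the 3-D shape-feature space."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    @property
    def mean_area(self) -> float:
        return float(self.mu[0])

    @property
    def sigma_inv(self) -> np.ndarray:
        # cached lazily; dataclass is frozen so stash via object.__setattr__
        cached = getattr(self, "_sigma_inv", None)
        if cached is None:
            cached = np.linalg.inv(self.sigma)
            object.__setattr__(self, "_sigma_inv", cached)
        return cached

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"mu": self.mu.tolist(), "sigma": self.sigma.tolist(), "n": self.n}
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ShapeModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        return cls(
            mu=np.asarray(data["mu"], dtype=np.float64),
            sigma=np.asarray(data["sigma"], dtype=np.float64),
            n=int(data["n"]),
        )


def features_of_coords(rows: np.ndarray, cols: np.ndarray) -> FeatureVector:
    """Shape features of a pixel set given by its (row, col) coordinates.

    The normalized second central moment matrix uses the +1/12 pixel-grid
    correction (each pixel is a unit square, not a point), matching the
    standard region-properties convention, so a single pixel already has a
    finite axis length.
    """
    n = rows.size
    if n < MIN_REGION_PIXELS:
        raise ValueError(f"region has {n} pixels; need >= {MIN_REGION_PIXELS}")
    r = rows - rows.mean()
    c = cols - cols.mean()
    mrr = (r @ r) / n + 1.0 / 12.0
    mcc = (c @ c) / n + 1.0 / 12.0
    mrc = (r @ c) / n
    # eigenvalues of [[mrr, mrc], [mrc, mcc]] in closed form
    tr, det = mrr + mcc, mrr * mcc - mrc * mrc
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = max(tr - lam1, 0.0)
    return FeatureVector(area=float(n), major=4.0 * np.sqrt(lam1), minor=4.0 * np.sqrt(lam2))


def region_features(mask: np.ndarray, label: int) -> FeatureVector:
    """Shape features of one labeled object in a mask."""
    rows, cols = np.nonzero(mask == label)
    if rows.size == 0:
        raise ValueError(f"label {label} not present in mask")
    return features_of_coords(rows.astype(np.float64), cols.astype(np.float64))


def all_region_features(mask: np.ndarray) -> dict[int, FeatureVector]:
    """Features for every positive label, skipping regions that are too small."""
    mask = np.asarray(mask)
    out: dict[int, FeatureVector] = {}
    for label, sl in enumerate(ndimage.find_objects(mask), start=1):
        if sl is None:
            continue
        rows, cols = np.nonzero(mask[sl] == label)
        if rows.size < MIN_REGION_PIXELS:
            continue
        out[label] = features_of_coords(
            rows.astype(np.float64) + sl[0].start, cols.astype(np.float64) + sl[1].start
        )
    return out


def _mean_cov(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False, bias=False)
    ridge = RIDGE_FRACTION * np.trace(sigma) / 3.0
    if ridge <= 0 or not np.isfinite(ridge):
        ridge = 1e-12
    sigma = sigma + max(ridge, 1e-12) * np.eye(3)
    return mu, sigma


def fit_shape_model(
    features: list[FeatureVector] | np.ndarray,
    max_cell_area: float | None = None,
    min_object_area: float | None = None,
    trim_fraction: float = 0.05,
) -> ShapeModel:
    """Fit the Gaussian shape model with contamination-robust trimming.

    The initial segmentation is only partially correct, so estimation
    trims: objects outside ``[min_object_area, max_cell_area]`` are
    excluded outright (under-segmentation suspects and debris), then the
    ``trim_fraction`` of objects with the largest Mahalanobis distance
    under an untrimmed fit are dropped and the model refit once.
    """
    if isinstance(features, np.ndarray):
        x = np.asarray(features, dtype=np.float64)
    else:
        x = np.array([f.as_array() for f in features], dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("features must be n x 3")
    if max_cell_area is not None:
        x = x[x[:, 0] <= max_cell_area]
    if min_object_area is not None:
        x = x[x[:, 0] >= min_object_area]
    if x.shape[0] < MIN_FIT_OBJECTS:
        raise ValueError(
            f"only {x.shape[0]} usable objects (need >= {MIN_FIT_OBJECTS}); "
            "the initial segmentation is too sparse -- review max_cell_area, "
            "the decomposition bound, or the foreground threshold window"
        )
    mu, sigma = _mean_cov(x)
    if trim_fraction > 0:
        diff = x - mu
        d = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(sigma), diff)
        keep = d <= np.quantile(d, 1.0 - trim_fraction)
        if keep.sum() >= MIN_FIT_OBJECTS:
            mu, sigma = _mean_cov(x[keep])
            x = x[keep]
    return ShapeModel(mu=mu, sigma=sigma, n=int(x.shape[0]))


def mahalanobis_D(x: FeatureVector | np.ndarray, model: ShapeModel) -> float:
    """Squared Mahalanobis distance of a feature vector under the model."""
    v = x.as_array() if isinstance(x, FeatureVector) else np.asarray(x, dtype=np.float64)
    diff = v - model.mu
    return float(diff @ model.sigma_inv @ diff)


def log_likelihood(x: FeatureVector | np.ndarray, model: ShapeModel) -> float:
    """Gaussian log-density; a decreasing affine function of mahalanobis_D."""
    d = 3
    sign, logdet = np.linalg.slogdet(model.sigma)
    if sign <= 0:
        raise ValueError("covariance is not positive definite")
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + mahalanobis_D(x, model))
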