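"""Pipeline configuration.

The segmentation pipeline exposes four free parameters that matter in
practice -- the maximum expected cell area, the number of edge-detection
scales, the lower bound of the threshold decomposition, and the window
size of the block-wise foreground threshold -- plus a handful of plumbing
knobs (connectivity, small-object floor, imaging modality, RNG seed).
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config"]

_MODALITIES = ("fluorescence", "phase_contrast")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Settings for the full segmentation pipeline.

    Attributes
    ----------
    max_cell_area:
        Upper bound on a plausible single-cell area, in pixels^2.  Objects
        larger than this are decomposed further / considered for splitting.
    max_scale:
        Number of scales ``S`` of the multi-scale edge detector; edge votes
        range over ``0..S``.  Should be smaller than the cell width.
    decomposition_bound:
        Lowest edge threshold ``f_min`` the recursive threshold
        decomposition may reach (``1 <= f_min <= max_scale``).
    threshold_window:
        Side length, in pixels, of the blocks used by the block-wise Otsu
        foreground threshold.  The largest window with homogeneous
        illumination is optimal.
    modality:
        ``"fluorescence"`` (bright cells on dark background) or
        ``"phase_contrast"`` (dark cells with bright halos).
    min_object_area:
        Objects below this area (pixels^2) are discarded as false positives.
    connectivity:
        Pixel connectivity (4 or 8) used for component labeling.
    rng_seed:
        Seed for any stochastic step (none in the default pipeline; kept so
        runs are reproducible end to end when sampling is enabled).
    """

    max_cell_area: int = 500
    max_scale: int = 5
    decomposition_bound: int = 2
    threshold_window: int = 64
    modality: str = "fluorescence"
    min_object_area: int = 25
    connectivity: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_scale < 1:
            raise ValueError("max_scale must be >= 1")
        if not (1 <= self.decomposition_bound <= self.max_scale):
            raise ValueError(
                f"decomposition_bound must satisfy 1 <= f_min <= S "
                f"(got f_min={self.decomposition_bound}, S={self.max_scale})"
            )
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if self.max_cell_area <= self.min_object_area:
            raise ValueError("max_cell_area must exceed min_object_area")
        if self.threshold_window < 16:
            raise ValueError("threshold_window must be >= 16")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# accepted aliases for config keys (short names used in the CLI / literature)
_ALIASES = {
    "s": "max_scale",
    "scales": "max_scale",
    "f_min": "decomposition_bound",
    "decomp_bound": "decomposition_bound",
    "window": "threshold_window",
    "seed": "rng_seed",
}

_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def _coerce(name: str, value: Any) -> Any:
    field = _FIELDS[name]
    if field.type in ("int", int):
        if isinstance(value, bool) or not isinstance(value, (int, float, str)):
            raise ValueError(f"config field {name!r}: expected a number, got {value!r}")
        as_float = float(value)
        if as_float != int(as_float):
            raise ValueError(f"config field {name!r}: expected an integer, got {value!r}")
        return int(as_float)
    return str(value)


def load_config(path: str | Path | None = None, text: str | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML key-value file.

    Missing keys take the documented defaults; unknown keys and invariant
    violations raise ``ValueError``.
    """
    if (path is None) == (text is None):
        raise ValueError("provide exactly one of path or text")
    raw = Path(path).read_text() if path is not None else text
    data = yaml.safe_load(io.StringIO(raw)) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a key-value mapping")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        name = _ALIASES.get(str(key).lower(), str(key).lower())
        if name not in _FIELDS:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[name] = _coerce(name, value)
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; round-trips through :func:`load_config`."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
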