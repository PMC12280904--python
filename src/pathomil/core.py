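"""Core domain containers shared across the pipeline.

The pipeline moves data through three representations: image tiles
(:class:`RGBPatch`), per-slide bags of patch-level survival likelihoods
(:class:`SlideLikelihoods`, the multi-instance "bag"), and cohort-level
survival tables (plain :class:`pandas.DataFrame` objects validated by
:func:`pathomil.io.read_cohort`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBPatch",
    "SlideLikelihoods",
    "PathomilError",
    "DegenerateHistogramError",
    "StainEstimationError",
    "MissingFeatureError",
    "CohortSchemaError",
]


class PathomilError(Exception):
    """Base class for pipeline errors."""


class DegenerateHistogramError(PathomilError):
    """Raised when an intensity histogram has a single occupied level."""


class StainEstimationError(PathomilError):
    """Raised when a tile has too little stained tissue to estimate stain vectors."""


class MissingFeatureError(PathomilError, KeyError):
    """A model references a feature absent from the supplied matrix."""


class CohortSchemaError(PathomilError, ValueError):
    """A cohort table violates the required schema."""


@dataclass(frozen=True)
class RGBPatch:
    """One square RGB tile cut from a slide.

    ``origin_xy`` is the 0-based pixel coordinate of the top-left corner;
    the tile covers the half-open interval ``[x, x+size) x [y, y+size)``.
    The production tile size is 512 px; smaller sizes are allowed for
    mini-tile fixtures.
    """

    slide_id: str
    grid_row: int
    grid_col: int
    origin_xy: tuple[int, int]
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
            raise ValueError(f"patch pixels must be square HxWx3, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("patch intensities must lie in [0, 255]")
        if self.grid_row < 0 or self.grid_col < 0:
            raise ValueError("grid indices must be non-negative")
        size = px.shape[0]
        x, y = self.origin_xy
        if x % size or y % size:
            raise ValueError("origin must be a multiple of the tile size")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


@dataclass(frozen=True)
class SlideLikelihoods:
    """Per-slide bag of patch positive-class probabilities.

    The positive class is death-within-5-years throughout the package;
    ``probabilities[i]`` is that class's predicted probability for patch
    ``i`` in tile-manifest order, and ``predicted_labels[i]`` its argmax
    class in {0, 1}.
    """

    slide_id: str
    probabilities: np.ndarray
    predicted_labels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        y = np.asarray(self.predicted_labels)
        if p.ndim != 1 or y.shape != p.shape:
            raise ValueError("probabilities and predicted_labels must be equal-length 1-D")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if y.size and not np.isin(y, (0, 1)).all():
            raise ValueError("predicted labels must be 0 or 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "predicted_labels", y.astype(int))

    def __len__(self) -> int:
        return int(self.probabilities.size)
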