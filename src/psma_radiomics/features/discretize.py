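"""Fixed-bin-width gray-level discretization.

VOI intensities are discretized with a fixed bin width (default 0.25 SUV)
anchored at the VOI minimum: ``level(x) = floor((x - min) / w) + 1``, with
the maximum clamped into the top bin.  A constant VOI collapses to a single
level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedVOI", "discretize"]

DEFAULT_BIN_WIDTH_SUV = 0.25


@dataclass
class DiscretizedVOI:
    """Integer gray levels of a VOI plus the discretization provenance."""

    levels: np.ndarray  # int array, 0 outside the VOI
    mask: np.ndarray
    bin_width: float
    origin: float  # SUV_min of the VOI
    n_levels: int

    def voi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_SUV,
) -> DiscretizedVOI:
    """Discretize VOI voxel values into gray levels of fixed bin width."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values, dtype=float)
    if not mask.any():
        raise ValueError("VOI is empty")
    vmin = float(values[mask].min())
    vmax = float(values[mask].max())
    n_levels = int(np.floor((vmax - vmin) / bin_width)) + 1
    levels = np.zeros(values.shape, dtype=np.int64)
    raw = np.floor((values[mask] - vmin) / bin_width).astype(np.int64) + 1
    levels[mask] = np.clip(raw, 1, n_levels)
    return DiscretizedVOI(levels, mask, bin_width, vmin, n_levels)
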