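"""Fixed-bin-width intensity discretization.

Continuous intensities are binned as ``floor((x - min(ROI)) / w) + 1`` and
the occupied bins are then re-indexed to the consecutive levels
``1 .. N_g`` before any texture matrix is built; empty intermediate bins
are dropped.  Anchoring at the ROI minimum makes the level array invariant
to shifting all intensities by a multiple of the bin width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedRoi", "discretize", "discretize_array"]


@dataclass
class DiscretizedRoi:
    """Gray-level array of a masked ROI.

    ``levels`` is a 3-D integer array aligned with the ROI: 0 marks voxels
    outside the mask, in-mask voxels hold levels in ``1 .. n_levels``.
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))

    def masked_levels(self) -> np.ndarray:
        """Flat vector of the in-mask levels."""
        return self.levels[self.levels > 0]


def discretize_array(values: np.ndarray, mask: np.ndarray, bin_width: float) -> DiscretizedRoi:
    """Discretize a masked 3-D array with a fixed bin width."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    if not mask.any():
        raise ValueError("empty ROI: mask selects no voxels")
    roi = values[mask]
    raw = np.floor((roi - roi.min()) / float(bin_width)).astype(np.int64) + 1
    # re-index occupied bins to consecutive levels 1..Ng
    occupied, compact = np.unique(raw, return_inverse=True)
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[mask] = compact + 1
    return DiscretizedRoi(levels=levels, n_levels=int(len(occupied)), bin_width=float(bin_width))


def discretize(roi, bin_width: float = 25.0) -> DiscretizedRoi:
    """Discretize a masked ``ImageVolume`` (or ``(values, mask)`` pair)."""
    if isinstance(roi, tuple):
        values, mask = roi
    else:  # masked ImageVolume: NaN marks out-of-mask voxels
        values = np.asarray(roi.values, dtype=float)
        mask = ~np.isnan(values)
    return discretize_array(np.nan_to_num(np.asarray(values, dtype=float)), mask, bin_width)
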