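"""Shared helpers for texture-matrix construction.

Direction conventions: 3-D texture matrices are built over the 26-voxel
neighbourhood.  For pair-based matrices (GLCM, GLRLM) only the 13 unique
direction vectors are enumerated; the opposite orientation is folded in by
symmetrization (GLCM) or by counting each maximal run once (GLRLM).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# 13 unique 3-D direction vectors: one representative per +/- pair of the
# 26 neighbours at Chebyshev distance 1.
UNIT_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(UNIT_DIRECTIONS) == 13


def chebyshev_offsets(distance: int = 1) -> list[tuple[int, int, int]]:
    """All nonzero integer offsets with infinity norm <= distance."""
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    r = range(-distance, distance + 1)
    return [(dx, dy, dz) for dx in r for dy in r for dz in r if (dx, dy, dz) != (0, 0, 0)]


@lru_cache(maxsize=4096)
def pair_slices(shape: tuple[int, ...], offset: tuple[int, ...]):
    """Aligned slice pairs so that ``a[sl_a]`` neighbours ``a[sl_b]`` by ``offset``.

    Returns None when the offset exceeds the array extent on some axis
    (no voxel pairs exist).
    """
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if abs(d) >= n:
            return None
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def xlog2x(p: np.ndarray) -> np.ndarray:
    """Elementwise p*log2(p) with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def entropy_bits(p: np.ndarray, axis=None) -> np.ndarray:
    """Shannon entropy in bits of a (batch of) probability vector(s)."""
    return -xlog2x(p).sum(axis=axis)
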