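"""Neighbouring gray tone difference matrix (NGTDM) features.

For each in-mask voxel with at least one in-mask neighbour (Chebyshev
distance ``distance``), the absolute difference between its gray level and
the mean level of those neighbours is accumulated per level:
``s_i = sum |i - A(v)|`` over voxels v of level i, with ``n_i`` the voxel
count and ``p_i = n_i / N_vp``.  Isolated voxels (no in-mask neighbour) do
not participate.

Degenerate rules: coarseness is capped at 1e6 when ``sum p_i s_i`` is 0;
contrast is 0 for a single occupied level; busyness and strength are 0
when their denominators vanish.
"""

from __future__ import annotations

import numpy as np

from ._util import chebyshev_offsets, pair_slices
from .discretize import DiscretizedRoi
from .matrices import TextureMatrix

__all__ = ["NGTDM_NAMES", "build_ngtdm", "ngtdm_features", "COARSENESS_CAP"]

NGTDM_NAMES: tuple[str, ...] = (
    "ngtdm_Busyness",
    "ngtdm_Coarseness",
    "ngtdm_Complexity",
    "ngtdm_Contrast",
    "ngtdm_Strength",
)

# returned for coarseness when every voxel equals its neighbourhood mean
COARSENESS_CAP = 1e6


def build_ngtdm(droi: DiscretizedRoi, distance: int = 1) -> TextureMatrix:
    """Columns (n_i, s_i) per level, shape (Ng, 2)."""
    lev = droi.levels
    inmask = lev > 0
    nbr_sum = np.zeros(lev.shape, dtype=float)
    nbr_cnt = np.zeros(lev.shape, dtype=np.int64)
    for off in chebyshev_offsets(distance):
        sl = pair_slices(lev.shape, off)
        if sl is None:
            continue
        sa, sb = sl
        valid = inmask[sa] & inmask[sb]
        nbr_sum[sa] += np.where(valid, lev[sb], 0)
        nbr_cnt[sa] += valid
    ng = droi.n_levels
    part = inmask & (nbr_cnt > 0)
    levels = lev[part]
    diff = np.abs(levels - nbr_sum[part] / nbr_cnt[part])
    n_i = np.bincount(levels, minlength=ng + 1)[1:].astype(float)
    s_i = np.bincount(levels, weights=diff, minlength=ng + 1)[1:]
    return TextureMatrix("NGTDM", np.stack([n_i, s_i], axis=1))


def ngtdm_features(droi: DiscretizedRoi, distance: int = 1) -> dict[str, float]:
    M = build_ngtdm(droi, distance).entries
    n_i, s_i = M[:, 0], M[:, 1]
    n_vp = n_i.sum()
    if n_vp == 0:  # only isolated voxels
        return {
            "ngtdm_Busyness": 0.0,
            "ngtdm_Coarseness": COARSENESS_CAP,
            "ngtdm_Complexity": 0.0,
            "ngtdm_Contrast": 0.0,
            "ngtdm_Strength": 0.0,
        }
    p_i = n_i / n_vp
    i = np.arange(1, len(p_i) + 1, dtype=float)
    occ = p_i > 0
    ngp = int(occ.sum())
    io, po, so = i[occ], p_i[occ], s_i[occ]

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ngp > 1:
        dij2 = (io[:, None] - io[None, :]) ** 2
        contrast = float(
            (po[:, None] * po[None, :] * dij2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_vp)
        )
        busy_den = float(np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        dij = np.abs(io[:, None] - io[None, :])
        complexity = float(
            (dij * (po[:, None] * so[:, None] + po[None, :] * so[None, :])
             / (po[:, None] + po[None, :])).sum() / n_vp
        )
        s_sum = float(s_i.sum())
        strength = float(((po[:, None] + po[None, :]) * dij2).sum()) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_Busyness": busyness,
        "ngtdm_Coarseness": min(coarseness, COARSENESS_CAP),
        "ngtdm_Complexity": complexity,
        "ngtdm_Contrast": contrast,
        "ngtdm_Strength": strength,
    }
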