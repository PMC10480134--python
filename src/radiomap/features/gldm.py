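"""Gray level dependence matrix (GLDM) features.

The dependence of a voxel is the number of its in-mask neighbours within a
Chebyshev distance whose gray level differs by at most ``alpha``.  The
matrix D(i, j) counts voxels of level i with dependence j - 1 (the column
index is shifted by one so size-style emphasis weights stay positive).
"""

from __future__ import annotations

import numpy as np

from ._util import chebyshev_offsets, pair_slices, xlog2x
from .discretize import DiscretizedRoi
from .matrices import TextureMatrix

__all__ = ["GLDM_NAMES", "build_gldm", "gldm_features"]

GLDM_NAMES: tuple[str, ...] = (
    "gldm_DependenceEntropy",
    "gldm_DependenceNonUniformity",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_DependenceVariance",
    "gldm_GrayLevelNonUniformity",
    "gldm_GrayLevelVariance",
    "gldm_HighGrayLevelEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceLowGrayLevelEmphasis",
    "gldm_LowGrayLevelEmphasis",
    "gldm_SmallDependenceEmphasis",
    "gldm_SmallDependenceHighGrayLevelEmphasis",
    "gldm_SmallDependenceLowGrayLevelEmphasis",
)


def dependence_counts(droi: DiscretizedRoi, alpha: float = 0.0, distance: int = 1) -> np.ndarray:
    """Per-voxel dependence counts (in-mask voxels; 0 elsewhere is meaningless)."""
    lev = droi.levels
    inmask = lev > 0
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in chebyshev_offsets(distance):
        sl = pair_slices(lev.shape, off)
        if sl is None:
            continue
        sa, sb = sl
        dep[sa] += inmask[sa] & inmask[sb] & (np.abs(lev[sa] - lev[sb]) <= alpha)
    return dep


def build_gldm(droi: DiscretizedRoi, alpha: float = 0.0, distance: int = 1) -> TextureMatrix:
    """Dependence counts D(level, dependence+1), shape (Ng, Dmax+1)."""
    lev = droi.levels
    inmask = lev > 0
    dep = dependence_counts(droi, alpha, distance)
    ng = droi.n_levels
    dmax = int(dep[inmask].max())
    D = np.zeros((ng, dmax + 1))
    np.add.at(D, (lev[inmask] - 1, dep[inmask]), 1.0)
    return TextureMatrix("GLDM", D)


def gldm_features(droi: DiscretizedRoi, alpha: float = 0.0, distance: int = 1) -> dict[str, float]:
    D = build_gldm(droi, alpha, distance).entries
    ng, nd = D.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)  # dependence + 1
    nz = D.sum()  # equals the voxel count: every voxel has one dependence
    p = D / nz
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_g = (pg * i).sum()
    mu_d = (pd * j).sum()
    return {
        "gldm_DependenceEntropy": float(-xlog2x(p).sum()),
        "gldm_DependenceNonUniformity": float((D.sum(axis=0) ** 2).sum() / nz),
        "gldm_DependenceNonUniformityNormalized": float((pd**2).sum()),
        "gldm_DependenceVariance": float((pd * (j - mu_d) ** 2).sum()),
        "gldm_GrayLevelNonUniformity": float((D.sum(axis=1) ** 2).sum() / nz),
        "gldm_GrayLevelVariance": float((pg * (i - mu_g) ** 2).sum()),
        "gldm_HighGrayLevelEmphasis": float((pg * i**2).sum()),
        "gldm_LargeDependenceEmphasis": float((pd * j**2).sum()),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float(
            (p * (i[:, None] ** 2 * j[None, :] ** 2)).sum()
        ),
        "gldm_LargeDependenceLowGrayLevelEmphasis": float(
            (p * (j[None, :] ** 2 / i[:, None] ** 2)).sum()
        ),
        "gldm_LowGrayLevelEmphasis": float((pg / i**2).sum()),
        "gldm_SmallDependenceEmphasis": float((pd / j**2).sum()),
        "gldm_SmallDependenceHighGrayLevelEmphasis": float(
            (p * (i[:, None] ** 2 / j[None, :] ** 2)).sum()
        ),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float(
            (p / (i[:, None] ** 2 * j[None, :] ** 2)).sum()
        ),
    }
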