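"""Gray level size zone matrix (GLSZM) features.

Zones are connected components of equal gray level under 26-connectivity;
the matrix S(i, z) counts zones of level i and size z.  The family is
direction-free, so no averaging is involved.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._util import xlog2x
from .discretize import DiscretizedRoi
from .matrices import TextureMatrix

__all__ = ["GLSZM_NAMES", "build_glszm", "glszm_features"]

GLSZM_NAMES: tuple[str, ...] = (
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_GrayLevelVariance",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_SmallAreaEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_ZoneEntropy",
    "glszm_ZonePercentage",
    "glszm_ZoneVariance",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def build_glszm(droi: DiscretizedRoi) -> TextureMatrix:
    """Zone counts S(level, size), shape (Ng, Zmax)."""
    ng = droi.n_levels
    if droi.n_voxels == 0:
        raise ValueError("empty ROI")
    per_level_sizes: list[np.ndarray] = []
    zmax = 1
    for level in range(1, ng + 1):
        labeled, n_zones = ndimage.label(droi.levels == level, structure=_STRUCT_26)
        sizes = np.bincount(labeled.ravel())[1:] if n_zones else np.array([], dtype=int)
        per_level_sizes.append(sizes)
        if sizes.size:
            zmax = max(zmax, int(sizes.max()))
    S = np.zeros((ng, zmax))
    for level, sizes in enumerate(per_level_sizes):
        if sizes.size:
            S[level] += np.bincount(sizes, minlength=zmax + 1)[1:]
    return TextureMatrix("GLSZM", S)


def glszm_features(droi: DiscretizedRoi) -> dict[str, float]:
    S = build_glszm(droi).entries  # (Ng, Zmax)
    n_p = droi.n_voxels
    ng, zmax = S.shape
    i = np.arange(1, ng + 1, dtype=float)
    z = np.arange(1, zmax + 1, dtype=float)
    nz = S.sum()
    p = S / nz
    pg = p.sum(axis=1)
    pz = p.sum(axis=0)
    mu_g = (pg * i).sum()
    mu_z = (pz * z).sum()
    return {
        "glszm_GrayLevelNonUniformity": float((S.sum(axis=1) ** 2).sum() / nz),
        "glszm_GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "glszm_GrayLevelVariance": float((pg * (i - mu_g) ** 2).sum()),
        "glszm_HighGrayLevelZoneEmphasis": float((pg * i**2).sum()),
        "glszm_LargeAreaEmphasis": float((pz * z**2).sum()),
        "glszm_LargeAreaHighGrayLevelEmphasis": float(
            (p * (i[:, None] ** 2 * z[None, :] ** 2)).sum()
        ),
        "glszm_LargeAreaLowGrayLevelEmphasis": float(
            (p * (z[None, :] ** 2 / i[:, None] ** 2)).sum()
        ),
        "glszm_LowGrayLevelZoneEmphasis": float((pg / i**2).sum()),
        "glszm_SizeZoneNonUniformity": float((S.sum(axis=0) ** 2).sum() / nz),
        "glszm_SizeZoneNonUniformityNormalized": float((pz**2).sum()),
        "glszm_SmallAreaEmphasis": float((pz / z**2).sum()),
        "glszm_SmallAreaHighGrayLevelEmphasis": float(
            (p * (i[:, None] ** 2 / z[None, :] ** 2)).sum()
        ),
        "glszm_SmallAreaLowGrayLevelEmphasis": float(
            (p / (i[:, None] ** 2 * z[None, :] ** 2)).sum()
        ),
        "glszm_ZoneEntropy": float(-xlog2x(p).sum()),
        "glszm_ZonePercentage": float(nz / n_p),
        "glszm_ZoneVariance": float((pz * (z - mu_z) ** 2).sum()),
    }
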