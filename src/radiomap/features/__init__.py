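"""The 93-entry radiomic feature registry and the combined extractor.

Families and counts: 18 first-order, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM
and 5 NGTDM features, named in the ``family_FeatureName`` style.  Shape
features are deliberately absent: the analyses this package supports vary
the VOI size on purpose, so geometric descriptors of the VOI itself carry
no information about the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discretize import DiscretizedRoi, discretize, discretize_array
from .firstorder import FIRSTORDER_NAMES, RoiSample, first_order_features
from .glcm import GLCM_NAMES, build_glcm, glcm_features
from .gldm import GLDM_NAMES, build_gldm, gldm_features
from .glrlm import GLRLM_NAMES, build_glrlm, glrlm_features
from .glszm import GLSZM_NAMES, build_glszm, glszm_features
from .matrices import TextureMatrix
from .ngtdm import NGTDM_NAMES, build_ngtdm, ngtdm_features

__all__ = [
    "FEATURE_NAMES",
    "FAMILY_NAMES",
    "ExtractionSettings",
    "extract_all",
    "extract_from_arrays",
    "RoiSample",
    "DiscretizedRoi",
    "TextureMatrix",
    "discretize",
    "discretize_array",
    "first_order_features",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "build_gldm",
    "gldm_features",
    "build_ngtdm",
    "ngtdm_features",
]

FAMILY_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

#: Registry order: first-order, then the matrix families alphabetically.
FEATURE_NAMES: tuple[str, ...] = (
    FIRSTORDER_NAMES + GLCM_NAMES + GLDM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES
)
assert len(FEATURE_NAMES) == 93 and len(set(FEATURE_NAMES)) == 93


@dataclass(frozen=True)
class ExtractionSettings:
    """Extraction parameters shared by every feature family.

    ``bin_width`` is the fixed intensity bin width of the discretization
    (default 25, the widely used recommendation for unnormalized images);
    distances are in voxels (Chebyshev).
    """

    bin_width: float = 25.0
    glcm_distance: int = 1
    gldm_alpha: float = 0.0
    gldm_distance: int = 1
    ngtdm_distance: int = 1

    def fingerprint(self) -> str:
        return (
            f"bw{self.bin_width:g}_glcmd{self.glcm_distance}"
            f"_gldma{self.gldm_alpha:g}d{self.gldm_distance}_ngtdmd{self.ngtdm_distance}"
        )


def extract_from_arrays(
    values: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float = 1.0,
    settings: ExtractionSettings | None = None,
    names: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Compute the registry features of a masked 3-D intensity array.

    ``names`` restricts the output to a registry subset (whole families
    are skipped when none of their features is requested); the default is
    the full ordered 93-entry registry.
    """
    s = settings or ExtractionSettings()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    wanted = FEATURE_NAMES if names is None else tuple(names)
    families = {n.split("_", 1)[0] for n in wanted}
    droi = discretize_array(values, mask, s.bin_width)
    out: dict[str, float] = {}
    if "firstorder" in families:
        sample = RoiSample(np.asarray(values, dtype=float)[mask], voxel_volume)
        out.update(first_order_features(sample, s.bin_width, droi=droi))
    if "glcm" in families:
        out.update(glcm_features(droi, s.glcm_distance))
    if "gldm" in families:
        out.update(gldm_features(droi, s.gldm_alpha, s.gldm_distance))
    if "glrlm" in families:
        out.update(glrlm_features(droi))
    if "glszm" in families:
        out.update(glszm_features(droi))
    if "ngtdm" in families:
        out.update(ngtdm_features(droi, s.ngtdm_distance))
    return {name: out[name] for name in wanted}


def extract_all(roi, settings: ExtractionSettings | None = None) -> dict[str, float]:
    """Compute all 93 features of a masked ``ImageVolume``.

    ``roi`` is an ``ImageVolume`` whose out-of-mask voxels are NaN, or a
    ``(volume, mask_volume)`` pair.
    """
    if isinstance(roi, tuple):
        vol, mask_vol = roi
        values = np.asarray(vol.values, dtype=float)
        mask = np.asarray(mask_vol.values, dtype=bool)
        voxel_volume = vol.geometry.voxel_volume
    else:
        values = np.asarray(roi.values, dtype=float)
        mask = ~np.isnan(values)
        voxel_volume = roi.geometry.voxel_volume
    return extract_from_arrays(np.nan_to_num(values), mask, voxel_volume, settings)
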