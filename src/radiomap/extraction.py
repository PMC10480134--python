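"""Feature extraction by the two rival routes.

Conventional extraction computes the 93 features directly from the source
voxels inside a sphere VOI.  Map extraction "copies" the same physical
sphere onto the coarse map grid — the sphere is re-rasterized on the map
geometry, not resampled — and reports, per feature, the arithmetic mean of
the non-missing map voxels whose centres fall inside it.
"""

from __future__ import annotations

import numpy as np

from .features import ExtractionSettings, extract_from_arrays
from .geometry import ImageVolume, SphereVOI
from .maps import FeatureMapStack
from .voi import rasterize_sphere

__all__ = ["conventional_extract", "map_extract", "MapCoverageError"]


class MapCoverageError(ValueError):
    """The sphere covers no usable (non-missing) map voxel centre.

    Small spheres on a coarse block grid can miss every map-voxel centre;
    this is a real limitation of map-based extraction at small VOI sizes
    and is reported, never silently imputed.
    """


def conventional_extract(
    volume: ImageVolume,
    voi: SphereVOI,
    settings: ExtractionSettings | None = None,
    names: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Registry features from the source voxels inside the sphere."""
    mask = rasterize_sphere(voi, volume.geometry)
    return extract_from_arrays(
        np.asarray(volume.values, dtype=float),
        mask.values,
        volume.geometry.voxel_volume,
        settings,
        names,
    )


def map_extract(stack: FeatureMapStack, voi: SphereVOI) -> dict[str, float]:
    """Mean of each feature map over the copied sphere VOI.

    The same physical sphere is used for every map; missing (NaN) map
    voxels are excluded from the mean.

    Raises
    ------
    MapCoverageError
        If the sphere covers no map-voxel centre, or only missing ones.
    """
    geom = stack.grid.map_geometry
    try:
        mask = rasterize_sphere(voi, geom)
    except ValueError as exc:
        raise MapCoverageError(
            f"{voi.diameter} mm sphere at {voi.center} covers no map-voxel centre "
            f"(map spacing {geom.spacing} mm)"
        ) from exc
    m = mask.values
    out: dict[str, float] = {}
    for name, vol in stack.maps.items():
        vals = np.asarray(vol.values, dtype=float)[m]
        finite = np.isfinite(vals)
        if not finite.any():
            raise MapCoverageError(
                f"{voi.diameter} mm sphere covers only missing voxels of map {name!r}"
            )
        out[name] = float(vals[finite].mean())
    return out


def map_support(stack: FeatureMapStack, voi: SphereVOI) -> int:
    """Number of non-missing map voxels whose centres lie inside the sphere."""
    try:
        mask = rasterize_sphere(voi, stack.grid.map_geometry)
    except ValueError:
        return 0
    first = next(iter(stack.maps.values()))
    return int(np.isfinite(np.asarray(first.values, dtype=float)[mask.values]).sum())
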