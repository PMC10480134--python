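"""Sphere-VOI rasterization and placement in physical coordinates.

The inclusion rule is voxel-centred: a voxel belongs to the mask iff its
physical centre lies strictly within ``diameter / 2`` of the sphere centre
(Euclidean distance in mm).  The rule is shared by every module so that the
same physical sphere rasterized on the fine image grid and on the coarse
map grid selects geometrically consistent supports.
"""

from __future__ import annotations

import numpy as np

from .geometry import ImageVolume, SphereVOI, VolumeGeometry

__all__ = ["rasterize_sphere", "place_concentric_vois", "PlacementError"]


class PlacementError(RuntimeError):
    """No feasible VOI centre was found within the attempt cap."""


def rasterize_sphere(voi: SphereVOI, geometry: VolumeGeometry) -> ImageVolume:
    """Rasterize a physical-space sphere onto a grid as a binary mask.

    Parameters
    ----------
    voi : SphereVOI
        Sphere centre (mm) and diameter (mm).
    geometry : VolumeGeometry
        Target grid; the mask shares it.

    Returns
    -------
    ImageVolume
        Boolean mask, 1 where the voxel centre is inside the sphere.

    Raises
    ------
    ValueError
        If no voxel centre falls inside the sphere (the sphere misses the
        grid entirely or slips between voxel centres).
    """
    r2 = voi.radius**2
    d2 = np.zeros(geometry.shape, dtype=float)
    for axis in range(3):
        delta = geometry.voxel_centers(axis) - voi.center[axis]
        shape = [1, 1, 1]
        shape[axis] = -1
        d2 = d2 + (delta**2).reshape(shape)
    mask = d2 < r2
    if not mask.any():
        raise ValueError(
            f"sphere (center={voi.center}, d={voi.diameter} mm) covers no voxel centre "
            f"of the {geometry.shape} grid"
        )
    return ImageVolume(mask, geometry)


def _sphere_fits(center: np.ndarray, radius: float, geometry: VolumeGeometry, margin: float) -> bool:
    lo = np.asarray(geometry.origin)
    hi = lo + np.asarray(geometry.extent)
    return bool(np.all(center - radius - margin >= lo) and np.all(center + radius + margin <= hi))


def place_concentric_vois(
    volume: ImageVolume,
    vessel_mask: ImageVolume | None,
    diameters: tuple[float, ...] = (10.0, 20.0, 30.0),
    margin: float = 2.0,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 2000,
) -> list[SphereVOI]:
    """Place one set of concentric sphere VOIs avoiding vessels.

    The centre is drawn by seeded rejection sampling until the largest
    sphere lies fully inside the volume (with ``margin`` mm clearance from
    the boundary) and its rasterized mask has zero overlap with the vessel
    mask.  All diameters share the accepted centre, so VOI size is the only
    factor that varies between the returned spheres.

    Raises
    ------
    PlacementError
        If no feasible centre is found in ``max_attempts`` draws.
    """
    diameters = tuple(sorted(float(d) for d in diameters))
    if not diameters or diameters[0] <= 0:
        raise ValueError("diameters must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = volume.geometry
    r_max = diameters[-1] / 2.0
    lo = np.asarray(geom.origin) + r_max + margin
    hi = np.asarray(geom.origin) + np.asarray(geom.extent) - r_max - margin
    if np.any(hi <= lo):
        raise PlacementError(
            f"volume extent {geom.extent} mm cannot host a {diameters[-1]} mm sphere "
            f"with {margin} mm margin"
        )
    vessels = None if vessel_mask is None else vessel_mask.values.astype(bool)
    for _ in range(max_attempts):
        center = rng.uniform(lo, hi)
        big = rasterize_sphere(SphereVOI(tuple(center), diameters[-1]), geom)
        if vessels is not None and bool((big.values & vessels).any()):
            continue
        return [SphereVOI(tuple(center), d) for d in diameters]
    raise PlacementError(
        f"no vessel-free centre for a {diameters[-1]} mm sphere in {max_attempts} attempts"
    )
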