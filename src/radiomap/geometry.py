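"""Volume geometry, image containers and sphere VOI specifications.

All physical computations in this package are done in millimetres via a
:class:`VolumeGeometry`; voxel indices never carry physical meaning on their
own.  Arrays are stored in ``(x, y, z)`` axis order with ``z`` the slice
axis.  The index-to-physical convention is voxel-centred with the origin at
the corner of voxel ``(0, 0, 0)``: the centre of voxel ``(i, j, k)`` is
``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGeometry", "ImageVolume", "SphereVOI"]


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid geometry of a 3-D scalar volume.

    Parameters
    ----------
    spacing : tuple of float
        Per-axis voxel edge length in mm; strictly positive.
    origin : tuple of float
        Physical position (mm) of the corner of voxel (0, 0, 0).
    shape : tuple of int
        Voxel counts per axis.
    """

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if len(self.spacing) != 3 or len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("geometry is 3-D: spacing, origin and shape need 3 entries")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 0 for n in self.shape):
            raise ValueError(f"shape must be nonnegative, got {self.shape}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths of the volume in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.spacing)


@dataclass
class ImageVolume:
    """A 3-D scalar array plus its physical geometry.

    ``values`` may contain NaN as the missing-value marker (used by the
    coarse feature maps for partial edge blocks).
    """

    values: np.ndarray
    geometry: VolumeGeometry = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"ImageVolume payload must be 3-D, got {self.values.ndim}-D")
        if self.geometry is None:
            self.geometry = VolumeGeometry(spacing=(1.0, 1.0, 1.0), shape=self.values.shape)
        if tuple(self.values.shape) != tuple(self.geometry.shape):
            raise ValueError(
                f"array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)

    def astype(self, dtype) -> "ImageVolume":
        return ImageVolume(self.values.astype(dtype), self.geometry)


@dataclass(frozen=True)
class SphereVOI:
    """Sphere volume of interest in physical space.

    The study configuration uses diameters of 10, 20 and 30 mm, but any
    positive diameter is accepted.
    """

    center: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "diameter", float(self.diameter))
        if len(self.center) != 3:
            raise ValueError("center must be a 3-vector (mm)")
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0
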