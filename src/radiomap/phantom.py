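"""Synthetic multi-subject, multi-scanner liver-like phantom volumes.

Each subject's parenchyma is a statistically stationary texture: a
Gaussian random field built by convolving white noise with a Gaussian
kernel of a physical correlation length (mm), standardized to the
subject's texture standard deviation, added to the subject's base mean,
plus independent voxelwise scanner noise, all scaled by the scanner gain.
Bright tubular vessel segments are embedded and recorded in a companion
mask so VOI placement can avoid them, mimicking how readers avoid large
vessels when segmenting normal parenchyma.

Between-subject heterogeneity (random base mean and texture SD per
subject) is mandatory: agreement coefficients over a cohort degenerate
when all subjects are exchangeable replicates.

Scanner presets differ only in geometry, gain and noise — no
pulse-sequence physics is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import ImageVolume, VolumeGeometry

__all__ = [
    "ScannerPreset",
    "SubjectParams",
    "CohortSpec",
    "default_presets",
    "sample_cohort",
    "render_subject",
]


@dataclass(frozen=True)
class ScannerPreset:
    """Acquisition geometry and noise of one scanner.

    ``slice_step`` is slice thickness plus inter-slice gap (mm); the z
    spacing of rendered volumes.  ``noise_sd`` is the voxelwise Gaussian
    noise level in intensity units before gain; ``global_gain`` a
    dimensionless intensity scale.
    """

    name: str
    in_plane_spacing: float = 1.125
    slice_step: float = 5.5
    noise_sd: float = 6.0
    global_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= 0 or self.slice_step <= 0:
            raise ValueError("spacings must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.in_plane_spacing, self.in_plane_spacing, self.slice_step)


def default_presets() -> list[ScannerPreset]:
    """Three presets: two 3-T-like scanners (5 mm slices + 0.5 mm gap) and
    one 1.5-T-like scanner (6 mm slices + 0.6 mm gap, noisier, lower gain)."""
    return [
        ScannerPreset("scanner1", 1.125, 5.5, noise_sd=6.0, global_gain=1.0),
        ScannerPreset("scanner2", 1.125, 5.5, noise_sd=4.0, global_gain=1.1),
        ScannerPreset("scanner3", 1.09375, 6.6, noise_sd=9.0, global_gain=0.85),
    ]


@dataclass(frozen=True)
class SubjectParams:
    """Tissue parameters of one synthetic subject."""

    subject_id: str
    base_mean: float
    texture_sd: float
    correlation_length: float
    vessel_count: int

    def __post_init__(self) -> None:
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be nonnegative")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions of the between-subject heterogeneity.

    ``mean_distribution`` and ``sd_distribution`` are (location, scale) of
    Gaussians for the subject base mean and texture SD (the latter clipped
    at 0); ``correlation_length_range`` is a uniform mm interval.  The seed
    fully determines the cohort.
    """

    n_subjects: int
    mean_distribution: tuple[float, float] = (300.0, 40.0)
    sd_distribution: tuple[float, float] = (25.0, 6.0)
    correlation_length_range: tuple[float, float] = (3.0, 6.0)
    vessel_count_range: tuple[int, int] = (2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("OCCC needs between-subject variance: n_subjects >= 2")
        if self.mean_distribution[1] < 0 or self.sd_distribution[1] < 0:
            raise ValueError("distribution scales must be nonnegative")
        if not (0 < self.correlation_length_range[0] <= self.correlation_length_range[1]):
            raise ValueError("invalid correlation_length_range")


def sample_cohort(spec: CohortSpec) -> list[SubjectParams]:
    """Draw the per-subject parameters; identical seed, identical cohort."""
    rng = np.random.default_rng(spec.seed)
    means = rng.normal(*spec.mean_distribution, size=spec.n_subjects)
    sds = np.clip(rng.normal(*spec.sd_distribution, size=spec.n_subjects), 0.0, None)
    cls = rng.uniform(*spec.correlation_length_range, size=spec.n_subjects)
    lo, hi = spec.vessel_count_range
    counts = rng.integers(lo, hi + 1, size=spec.n_subjects)
    return [
        SubjectParams(
            subject_id=f"subj{idx:03d}",
            base_mean=float(means[idx]),
            texture_sd=float(sds[idx]),
            correlation_length=float(cls[idx]),
            vessel_count=int(counts[idx]),
        )
        for idx in range(spec.n_subjects)
    ]


def _correlated_field(shape, spacing, correlation_length, rng) -> np.ndarray:
    """Unit-variance stationary Gaussian field with a physical kernel width."""
    white = rng.standard_normal(shape)
    sigma_vox = [correlation_length / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd == 0:  # pathological tiny volume
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _vessel_mask(shape, spacing, count, rng,
                 length_mm=(20.0, 40.0), radius_mm=(1.5, 3.0)) -> np.ndarray:
    """Rasterize bright tubular segments: random chords of finite length."""
    mask = np.zeros(shape, dtype=bool)
    if count == 0:
        return mask
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    sp = np.asarray(spacing)
    coords = None
    for _ in range(count):
        p0 = rng.uniform(0.1, 0.9, size=3) * extent
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(*length_mm)
        radius = rng.uniform(*radius_mm)
        a = p0 - direction * length / 2
        b = p0 + direction * length / 2
        if coords is None:
            coords = np.stack(
                np.meshgrid(*(((np.arange(n) + 0.5) * s) for n, s in zip(shape, sp)),
                            indexing="ij"),
                axis=-1,
            )
        ap = coords - a
        ab = b - a
        t = np.clip((ap @ ab) / (ab @ ab), 0.0, 1.0)
        nearest = a + t[..., None] * ab
        dist = np.linalg.norm(coords - nearest, axis=-1)
        mask |= dist <= radius
    return mask


def render_subject(
    params: SubjectParams,
    preset: ScannerPreset,
    shape: tuple[int, int, int] = (56, 56, 11),
    seed: int = 0,
    vessel_contrast: float = 120.0,
    min_voi_diameter: float = 30.0,
) -> tuple[ImageVolume, ImageVolume]:
    """Render one subject on one scanner.

    Returns ``(volume, vessel_mask)`` sharing one geometry.  The volume is
    ``gain * (base_mean + texture + vessels + noise)`` with the texture a
    correlated Gaussian field scaled to ``texture_sd`` and noise i.i.d.
    Gaussian of ``preset.noise_sd``.

    Raises
    ------
    ValueError
        If the physical extent cannot host a ``min_voi_diameter`` sphere.
    """
    geom = VolumeGeometry(spacing=preset.spacing, shape=shape)
    if min(geom.extent) < min_voi_diameter + 2.0:
        raise ValueError(
            f"volume extent {geom.extent} mm too small for a {min_voi_diameter} mm VOI"
        )
    rng = np.random.default_rng(seed)
    values = np.full(shape, params.base_mean, dtype=float)
    if params.texture_sd > 0:
        values += params.texture_sd * _correlated_field(
            shape, geom.spacing, params.correlation_length, rng
        )
    vessels = _vessel_mask(shape, geom.spacing, params.vessel_count, rng)
    values[vessels] += vessel_contrast
    if preset.noise_sd > 0:
        values += rng.normal(0.0, preset.noise_sd, size=shape)
    values *= preset.global_gain
    return ImageVolume(values, geom), ImageVolume(vessels, geom)


def write_cohort_manifest(path: str | Path, rows: list[dict]) -> Path:
    """CSV manifest (subject_id, scanner, seed, parameters) of a cohort."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
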