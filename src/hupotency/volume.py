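"""Recovering mass potency from CT volumes via the measured sample mass.

Powder samples have unknown packing density and irregular volume, but the
total mass M is easy to weigh.  Since mu* integrates the density field,

    M = Int rho dr  and  eta_rho = rho_water * Int mu* dr / M

gives an intensive, packing-independent estimate of the mass potency.  The
bottle wall is removed by subtracting the mu* integral of an identically
segmented empty bottle.  Segmentation is a simple HU threshold inside a
user-supplied region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .materials import WATER_DENSITY

__all__ = [
    "VoxelVolume",
    "SegmentationResult",
    "segment_bottle",
    "potency_from_mass",
    "threshold_sensitivity",
    "read_dicom_series",
]

#: Voxel spacing of the reference acquisition, metres.
DEFAULT_SPACING = (0.3125e-3, 0.3125e-3, 0.625e-3)


@dataclass(frozen=True)
class VoxelVolume:
    """3-D array of HU values with voxel spacing (m) and origin."""

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("volume must be 3-D")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        object.__setattr__(self, "values", values)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, m^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class SegmentationResult:
    """Thresholded mask and its mu* integral (m^3)."""

    mask: np.ndarray
    threshold: float
    integral_mu_star: float


def _roi_slices(
    volume: VoxelVolume, roi: Sequence[slice] | None
) -> tuple[slice, slice, slice]:
    if roi is None:
        return (slice(None), slice(None), slice(None))
    if len(roi) != 3:
        raise ValueError("roi must give one slice per axis")
    for ax, s in enumerate(roi):
        stop = s.stop if s.stop is not None else volume.values.shape[ax]
        if stop > volume.values.shape[ax] or (s.start or 0) < 0:
            raise ValueError("roi extends outside the volume")
    return tuple(roi)  # type: ignore[return-value]


def segment_bottle(
    volume: VoxelVolume,
    threshold: float,
    roi: Sequence[slice] | None = None,
) -> SegmentationResult:
    """Select voxels above an HU threshold inside a bounding box.

    The integral uses mu* = 1 + HU/1000 (water = 1, air ~ 0), summed over
    the mask and scaled by the voxel volume.
    """
    slices = _roi_slices(volume, roi)
    mask = np.zeros(volume.values.shape, dtype=bool)
    mask[slices] = volume.values[slices] > threshold
    if not mask.any():
        raise ValueError(f"threshold {threshold} HU selects no voxels in the ROI")
    mu = 1.0 + volume.values[mask] / 1000.0
    integral = float(mu.sum() * volume.voxel_volume)
    return SegmentationResult(mask=mask, threshold=threshold, integral_mu_star=integral)


def potency_from_mass(
    filled: SegmentationResult,
    empty: SegmentationResult,
    mass: float,
    water_density: float = WATER_DENSITY,
) -> float:
    """Mass HU potency from the net mu* integral and the weighed mass.

    eta_rho = rho_water * (Int mu*_filled - Int mu*_empty) / M.  The empty
    acquisition removes the bottle-wall contribution.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    net = filled.integral_mu_star - empty.integral_mu_star
    if net <= 0:
        raise ValueError("net mu* integral is not positive; check segmentation")
    return water_density * net / mass


def threshold_sensitivity(
    volume: VoxelVolume,
    empty: SegmentationResult,
    mass: float,
    center: float,
    full_range: float,
    roi: Sequence[slice] | None = None,
    water_density: float = WATER_DENSITY,
) -> float:
    """Max relative change of eta over thresholds in [center +/- range/2].

    Thresholds are sampled at 1 HU steps; the reported number is
    max_t |eta(t) - eta(center)| / eta(center).
    """
    if full_range <= 0:
        raise ValueError("threshold range must be positive")
    eta_center = potency_from_mass(
        segment_bottle(volume, center, roi), empty, mass, water_density
    )
    half = full_range / 2.0
    thresholds = np.arange(center - half, center + half + 0.5, 1.0)
    worst = 0.0
    for t in thresholds:
        eta = potency_from_mass(
            segment_bottle(volume, float(t), roi), empty, mass, water_density
        )
        worst = max(worst, abs(eta - eta_center) / eta_center)
    return worst


def read_dicom_series(directory) -> VoxelVolume:
    """Load an axial DICOM series into a VoxelVolume (requires pydicom)."""
    import pydicom  # optional dependency

    from pathlib import Path

    paths = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    slices = [pydicom.dcmread(p) for p in paths if p.is_file()]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    stack = np.stack(
        [ds.pixel_array * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
         for ds in slices],
        axis=-1,
    )
    first = slices[0]
    dy, dx = (float(v) * 1e-3 for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = abs(
            float(slices[1].ImagePositionPatient[2])
            - float(first.ImagePositionPatient[2])
        ) * 1e-3
    else:
        dz = float(getattr(first, "SliceThickness", 1.0)) * 1e-3
    origin = tuple(float(v) * 1e-3 for v in first.ImagePositionPatient)
    return VoxelVolume(stack.astype(float), spacing=(dx, dy, dz), origin=origin)
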