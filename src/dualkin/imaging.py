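"""Containers and spatial operations for dynamic volumetric imaging series.

This module holds the small data model the rest of the package is built on:
frame-timing schedules, 4D dynamic images, binary voxel masks and sampled
time curves, together with the handful of image-space operations the
analysis needs (Gaussian smoothing, mask intersection, VOI curve
extraction) and NIfTI/CSV I/O.

All images are assumed to live on a common, pre-registered isotropic grid
(registration is out of scope for this package); grid compatibility is
checked, never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "VoxelMask",
    "TimeCurve",
    "GridMismatchError",
    "EmptyIntersectionError",
    "EmptyMaskError",
    "frame_midpoints",
    "read_dynamic",
    "write_dynamic",
    "read_mask",
    "write_mask",
    "gaussian_smooth",
    "intersect_masks",
    "extract_voi_curve",
    "fwhm_to_sigma",
]

#: conversion factor between the full width at half maximum of a Gaussian
#: and its standard deviation: FWHM = 2*sqrt(2*ln 2) * sigma
FWHM_OVER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

VALID_UNITS = ("kBq/mL", "arbitrary-signal", "mM")


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class EmptyIntersectionError(ValueError):
    """Mask intersection left no analyzable voxels."""


class EmptyMaskError(ValueError):
    """A mask that must select at least one voxel selects none."""


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian FWHM to the equivalent standard deviation."""
    return float(fwhm) / FWHM_OVER_SIGMA


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start times and durations of a dynamic acquisition.

    Parameters
    ----------
    starts
        Frame start times in seconds, non-decreasing.
    durations
        Frame durations in seconds, strictly positive, one per start.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or durations.ndim != 1:
            raise ValueError("starts and durations must be 1-D")
        if starts.size != durations.size:
            raise ValueError(
                f"starts ({starts.size}) and durations ({durations.size}) "
                "must have the same length"
            )
        if starts.size == 0:
            raise ValueError("empty frame schedule")
        if np.any(durations <= 0):
            raise ValueError("all frame durations must be > 0")
        if np.any(np.diff(starts) < 0):
            raise ValueError("frame starts must be non-decreasing")

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        """Build a gap-free schedule from consecutive frame durations."""
        durations = np.asarray(durations, dtype=float)
        starts = t0 + np.concatenate(([0.0], np.cumsum(durations[:-1])))
        return cls(starts=starts, durations=durations)

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def total_duration(self) -> float:
        """Span from the first frame start to the last frame end."""
        return float(self.ends[-1] - self.starts[0])

    @property
    def is_contiguous(self) -> bool:
        """True when every frame starts exactly where the previous ends."""
        return bool(np.allclose(self.starts[1:], self.ends[:-1]))

    @classmethod
    def from_csv(cls, path) -> "FrameSchedule":
        df = pd.read_csv(path)
        return cls(
            starts=df["start_s"].to_numpy(float),
            durations=df["duration_s"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"start_s": self.starts, "duration_s": self.durations}).to_csv(
            path, index=False
        )


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoint times in seconds: ``start + duration / 2``.

    Midpoints are the nominal evaluation times of the kinetic models;
    they are strictly increasing for any valid gap-free schedule.
    """
    return schedule.midpoints


@dataclass
class DynamicImage:
    """A 4D dynamic image: a (x, y, z, frame) grid plus timing and units."""

    data: np.ndarray
    voxel_size: np.ndarray
    schedule: FrameSchedule
    units: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image data must be 4-D (x, y, z, frame)")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"grid has {self.data.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    @property
    def shape3d(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class VoxelMask:
    """A binary 3D voxel mask on the common analysis grid."""

    data: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be three positive lengths (mm)")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class TimeCurve:
    """A sampled curve over time (a TAC, an input function, ...)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TimeCurve":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(float), values=df["value"].to_numpy(float))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.asarray(voxel_size, dtype=float)
    return aff


def read_dynamic(path, schedule: FrameSchedule, units: str) -> DynamicImage:
    """Read a 4D NIfTI volume and attach the given frame schedule.

    The fourth dimension must match the schedule length; voxel sizes are
    taken from the header.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"{path}: file has {data.shape[3]} frames but schedule has "
            f"{schedule.n_frames}"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DynamicImage(data=data, voxel_size=voxel_size, schedule=schedule, units=units)


def write_dynamic(img: DynamicImage, path) -> None:
    nib.save(
        nib.Nifti1Image(img.data.astype(np.float64), _affine(img.voxel_size)), str(path)
    )


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a scalar 3D NIfTI volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    return data, np.asarray(img.header.get_zooms()[:3], dtype=float)


def write_volume(data: np.ndarray, voxel_size, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size)), str(path))


def read_mask(path) -> VoxelMask:
    """Read a binary NIfTI mask; any nonzero voxel is foreground."""
    data, voxel_size = read_volume(path)
    return VoxelMask(data=data != 0, voxel_size=voxel_size)


def write_mask(mask: VoxelMask, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size)), str(path)
    )


# ---------------------------------------------------------------------------
# Spatial operations


def gaussian_smooth(img: DynamicImage, fwhm_mm: float) -> DynamicImage:
    """Smooth every frame with a 3D isotropic Gaussian of the given FWHM.

    The kernel width is specified as FWHM in millimetres (the PET
    convention) and converted to per-axis standard deviations in voxels.
    Boundaries use reflect padding.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / img.voxel_size
    out = np.empty_like(img.data)
    for t in range(img.n_frames):
        ndimage.gaussian_filter(
            img.data[..., t], sigma=sigma_vox, mode="reflect", output=out[..., t]
        )
    return DynamicImage(
        data=out, voxel_size=img.voxel_size.copy(), schedule=img.schedule, units=img.units
    )


def _check_same_grid(a, b, what: str) -> None:
    if a.data.shape[:3] != b.data.shape[:3] or not np.allclose(
        a.voxel_size, b.voxel_size
    ):
        raise GridMismatchError(f"{what}: grids differ")


def intersect_masks(masks: list[VoxelMask]) -> VoxelMask:
    """Voxel-wise AND of several masks on the same grid.

    Raises :class:`EmptyIntersectionError` when no voxel survives, which
    would leave nothing to analyze downstream.
    """
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    combined = first.data.copy()
    for m in masks[1:]:
        _check_same_grid(first, m, "intersect_masks")
        combined &= m.data
    if not combined.any():
        raise EmptyIntersectionError("mask intersection is empty: no analyzable voxels")
    return VoxelMask(data=combined, voxel_size=first.voxel_size.copy())


def extract_voi_curve(img: DynamicImage, mask: VoxelMask) -> TimeCurve:
    """Mean value over the masked voxels for every frame.

    Times are the frame midpoints. Used both for tumor TAC inspection and
    for the image-derived input function from a blood-pool VOI.
    """
    if img.shape3d != mask.data.shape or not np.allclose(
        img.voxel_size, mask.voxel_size
    ):
        raise GridMismatchError("extract_voi_curve: image and mask grids differ")
    if mask.n_voxels == 0:
        raise EmptyMaskError("extract_voi_curve: mask selects no voxels")
    values = img.data[mask.data, :].mean(axis=0)
    return TimeCurve(times=img.schedule.midpoints, values=values)
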