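"""In-memory containers for 3D image data.

Array axes are ordered ``(z, y, x)`` throughout the package, matching the
page order of the multi-page TIFF interchange format, and voxel spacing is
the matching tuple ``(dz, dy, dx)`` in micrometres.  The ``z = 0`` face of a
stack is the apical (ependymal) surface by convention; a voxel with index
``(iz, iy, ix)`` has its centre at ``(iz*dz, iy*dy, ix*dx)`` micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid3D", "BinaryMask3D", "LabeledObjects"]


def _check_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(not np.isfinite(s) or s <= 0 for s in sp):
        raise ValueError(f"spacing must be three positive values, got {spacing!r}")
    return sp


@dataclass(frozen=True)
class VoxelGrid3D:
    """One channel of a 3D stack with (possibly anisotropic) voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if data.size == 0:
            raise ValueError("empty grid")
        if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
            raise ValueError("intensities must be finite")
        if np.any(data < 0):
            raise ValueError("intensities must be non-negative")
        data = data.copy()
        data.setflags(write=False)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1


@dataclass(frozen=True)
class BinaryMask3D:
    """Boolean foreground mask sharing geometry with its source grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        data = data.astype(bool, copy=True)
        data.setflags(write=False)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * self.voxel_volume_um3

    def same_geometry(self, other: "BinaryMask3D") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class LabeledObjects:
    """Integer-labelled connected components.

    Labels run contiguously from 1 (0 = background) and are sorted by
    descending voxel count; ties keep the scan order of the original
    labelling so the result is deterministic.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    voxel_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel: str = ""

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        labels = labels.astype(np.int32, copy=True)
        n = int(labels.max())
        counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        if self.voxel_counts is not None and not np.array_equal(counts, self.voxel_counts):
            raise ValueError("voxel_counts inconsistent with label image")
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "voxel_counts", counts)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def n_objects(self) -> int:
        return len(self.voxel_counts)

    @property
    def voxel_volumes_um3(self) -> np.ndarray:
        return self.voxel_counts * float(np.prod(self.spacing))
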