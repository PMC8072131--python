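"""Thresholding, niche-volume definition and connected components.

The niche (total tissue) volume — the denominator of every density — is
defined as the morphologically closed, per-slice hole-filled union of all
stained channels, so it is a deterministic function of the data; a
user-supplied mask can replace it.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import DegenerateHistogramError, EmptyNicheError
from .grids import BinaryMask3D, LabeledObjects, VoxelGrid3D

__all__ = ["segment_channel", "compute_niche_mask", "label_components", "ball_structure"]


def ball_structure(radius_um: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element: offsets within ``radius_um``."""
    dz, dy, dx = spacing
    rz = max(0, int(np.floor(radius_um / dz)))
    ry = max(0, int(np.floor(radius_um / dy)))
    rx = max(0, int(np.floor(radius_um / dx)))
    zz, yy, xx = np.meshgrid(
        np.arange(-rz, rz + 1) * dz,
        np.arange(-ry, ry + 1) * dy,
        np.arange(-rx, rx + 1) * dx,
        indexing="ij",
    )
    return zz**2 + yy**2 + xx**2 <= radius_um**2


def segment_channel(
    grid: VoxelGrid3D,
    method: str = "otsu",
    threshold: Optional[float] = None,
    smoothing_sigma_um: float = 0.0,
    opening_radius_um: float = 0.0,
) -> BinaryMask3D:
    """Threshold one intensity channel into a binary mask.

    Optional Gaussian pre-smoothing (sigma in um, converted per axis by
    the voxel spacing) precedes thresholding; voxels strictly above the
    threshold are foreground; a morphological opening with the given
    radius removes specks.  Otsu on a constant image raises
    :class:`DegenerateHistogramError`.
    """
    data = np.asarray(grid.data, dtype=np.float64)
    if smoothing_sigma_um > 0:
        sigmas = [smoothing_sigma_um / s for s in grid.spacing]
        data = ndimage.gaussian_filter(data, sigma=sigmas)
    if method == "otsu":
        if np.ptp(data) == 0:
            raise DegenerateHistogramError(
                f"channel {grid.channel!r}: constant intensity, Otsu threshold undefined"
            )
        thr = threshold_otsu(data)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = data > thr
    if opening_radius_um > 0:
        struct = ball_structure(opening_radius_um, grid.spacing)
        if struct.sum() > 1:
            mask = ndimage.binary_opening(mask, structure=struct)
    return BinaryMask3D(mask, grid.spacing, channel=grid.channel)


def compute_niche_mask(
    channel_masks: Sequence[BinaryMask3D], closing_radius_um: float = 5.0
) -> BinaryMask3D:
    """Total niche volume: closed, slice-hole-filled union of all channels.

    The result always contains every input mask (the union is OR-ed back
    in after closing, and closing is computed on a padded array so border
    voxels are never eroded away).
    """
    if not channel_masks:
        raise EmptyNicheError("no channel masks given")
    first = channel_masks[0]
    union = np.zeros(first.shape, dtype=bool)
    for m in channel_masks:
        if not first.same_geometry(m):
            raise ValueError("channel masks must share shape and spacing")
        union |= m.data
    if not union.any():
        raise EmptyNicheError("union of channel masks is empty")
    out = union
    if closing_radius_um > 0:
        struct = ball_structure(closing_radius_um, first.spacing)
        if struct.sum() > 1:
            pad = [(s // 2, s // 2) for s in struct.shape]
            padded = np.pad(union, pad, mode="constant")
            closed = ndimage.binary_closing(padded, structure=struct)
            sl = tuple(slice(p, p + n) for (p, _), n in zip(pad, union.shape))
            out = closed[sl] | union
    filled = np.empty_like(out)
    for iz in range(out.shape[0]):
        filled[iz] = ndimage.binary_fill_holes(out[iz])
    return BinaryMask3D(filled, first.spacing, channel="niche")


def label_components(
    mask: BinaryMask3D, connectivity: int = 26, min_size: int = 0
) -> LabeledObjects:
    """Connected components above ``min_size`` voxels, largest first."""
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    raw, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return LabeledObjects(raw, mask.spacing, channel=mask.channel)
    sizes = np.bincount(raw.ravel())[1:]
    keep = np.where(sizes >= max(min_size, 1))[0] + 1
    # stable sort: descending size, ascending original label on ties
    order = keep[np.lexsort((keep, -sizes[keep - 1]))]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    return LabeledObjects(remap[raw], mask.spacing, channel=mask.channel)
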