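"""Distance maps from the vessel surface and object-to-vessel minima.

The "vessel surface" is operationalised as the vessel foreground mask
itself (the laminin stain outlines the basement membrane at the vessel
surface), so distances are anisotropy-aware Euclidean distances to the
nearest vessel voxel.  Cells support centroid- and surface-based minima;
chains use their surface voxels as the source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cells import CellRecord
from .chains import ChainObject
from .exceptions import EmptyMaskError
from .grids import BinaryMask3D

__all__ = [
    "DistanceMap3D",
    "vessel_distance_map",
    "min_distance_cell",
    "min_distance_chain",
    "surface_voxels",
    "export_distance_preview",
]


@dataclass(frozen=True)
class DistanceMap3D:
    """Per-voxel um distance to the nearest vessel voxel."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        data.setflags(write=False)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self):
        return self.data.shape


def vessel_distance_map(vessel_mask: BinaryMask3D) -> DistanceMap3D:
    """Euclidean distance transform of the vessel-mask complement, in um."""
    if not vessel_mask.data.any():
        raise EmptyMaskError("distance map undefined for an empty vessel mask")
    dist = ndimage.distance_transform_edt(~vessel_mask.data, sampling=vessel_mask.spacing)
    return DistanceMap3D(dist, vessel_mask.spacing)


def surface_voxels(voxels: np.ndarray) -> np.ndarray:
    """Foreground voxels of an object with at least one 6-neighbour outside it."""
    vox = np.asarray(voxels)
    vset = set(map(tuple, vox))
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    keep = [
        v
        for v in map(tuple, vox)
        if any((v[0] + o[0], v[1] + o[1], v[2] + o[2]) not in vset for o in offs)
    ]
    return np.array(keep, dtype=vox.dtype).reshape(-1, 3)


def _min_over_voxels(voxels: np.ndarray, dmap: DistanceMap3D) -> float:
    return float(dmap.data[tuple(np.asarray(voxels).T)].min())


def min_distance_cell(cell: CellRecord, dmap: DistanceMap3D, mode: str = "surface") -> float:
    """Minimum cell-to-vessel distance in um.

    ``centroid`` reads the map at the voxel nearest the centroid;
    ``surface`` takes the minimum over the cell's boundary voxels (never
    larger than the centroid value).
    """
    if mode == "centroid":
        spacing = np.asarray(dmap.spacing, dtype=float)
        idx = np.round(np.asarray(cell.centroid_um, dtype=float) / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(dmap.shape)):
            raise ValueError("cell centroid lies outside the distance-map domain")
        return float(dmap.data[tuple(idx)])
    if mode == "surface":
        return _min_over_voxels(surface_voxels(cell.voxels), dmap)
    raise ValueError("mode must be 'centroid' or 'surface'")


def min_distance_chain(chain: ChainObject, dmap: DistanceMap3D) -> float:
    """Minimum map value over the chain's surface voxels."""
    d = _min_over_voxels(surface_voxels(chain.voxels), dmap)
    if d == 0.0:
        warnings.warn("chain overlaps the vessel mask; distance reported as 0", stacklevel=2)
    return d


def export_distance_preview(dmap: DistanceMap3D, path, vmax_um: float = 20.0):
    """Write a colour-coded minimum-intensity projection (0..vmax um ramp)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = dmap.data.min(axis=0)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(proj, cmap="turbo", vmin=0.0, vmax=vmax_um)
    fig.colorbar(im, ax=ax, label="distance to vessel (um)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
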