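"""Nucleus detection, marker classification and the apical filter.

A stem (type B) cell call is a DAPI nucleus whose voxel overlap with the
GFAP mask reaches a configurable fraction (default 0.3); "apical" cells
sit within 5 um of the ependymal surface (the z = 0 face by the package
convention, or a user-supplied reference surface for real data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import BinaryMask3D
from .segmentation import label_components

__all__ = ["CellRecord", "detect_nuclei", "classify_marker", "classify_gfap", "filter_apical", "count_marker"]


@dataclass
class CellRecord:
    """One detected nucleus and its derived attributes."""

    cell_id: int
    centroid_um: np.ndarray  # (z, y, x) um
    voxels: np.ndarray  # (n, 3) integer indices
    volume_um3: float
    apical_depth_um: float  # distance of the centroid from the apical surface
    gfap_fraction: float = float("nan")
    gfap_pos: bool = False
    ki67_pos: bool = False
    apical: Optional[bool] = None
    min_vessel_distance_um: float = float("nan")


def detect_nuclei(
    dapi_mask: BinaryMask3D,
    min_volume_um3: float = 20.0,
    max_volume_um3: float = 2000.0,
) -> list[CellRecord]:
    """Connected DAPI components within volume bounds become cell records."""
    labeled = label_components(dapi_mask, connectivity=26, min_size=0)
    spacing = np.asarray(dapi_mask.spacing, dtype=float)
    voxvol = dapi_mask.voxel_volume_um3
    records = []
    for lab in range(1, labeled.n_objects + 1):
        vox = np.argwhere(labeled.labels == lab)
        volume = len(vox) * voxvol
        if not (min_volume_um3 <= volume <= max_volume_um3):
            continue
        centroid = vox.astype(float).mean(axis=0) * spacing
        records.append(
            CellRecord(
                cell_id=len(records) + 1,
                centroid_um=centroid,
                voxels=vox,
                volume_um3=volume,
                apical_depth_um=float(centroid[0]),
            )
        )
    return records


def _overlap_fraction(voxels: np.ndarray, mask: np.ndarray) -> float:
    idx = tuple(voxels.T)
    return float(mask[idx].mean())


def classify_marker(
    cells: Sequence[CellRecord],
    marker_mask: BinaryMask3D,
    marker: str,
    overlap_threshold: float = 0.3,
) -> list[CellRecord]:
    """Set a marker flag per cell from nucleus/marker mask overlap.

    A cell is positive iff ``|nucleus ∩ marker| / |nucleus| >= threshold``
    (boundary inclusive).  Raising the threshold never adds positives.
    """
    if marker not in ("gfap", "ki67"):
        raise ValueError("marker must be 'gfap' or 'ki67'")
    for c in cells:
        frac = _overlap_fraction(c.voxels, marker_mask.data)
        pos = frac >= overlap_threshold
        if marker == "gfap":
            c.gfap_fraction = frac
            c.gfap_pos = pos
        else:
            c.ki67_pos = pos
    return list(cells)


def classify_gfap(
    cells: Sequence[CellRecord],
    gfap_mask: BinaryMask3D,
    overlap_threshold: float = 0.3,
) -> list[CellRecord]:
    return classify_marker(cells, gfap_mask, "gfap", overlap_threshold)


def filter_apical(cells: Sequence[CellRecord], apical_threshold_um: float = 5.0) -> list[CellRecord]:
    """Keep cells whose apical depth is at most the threshold (default 5 um)."""
    if apical_threshold_um < 0:
        raise ValueError("apical threshold must be non-negative")
    for c in cells:
        c.apical = c.apical_depth_um <= apical_threshold_um
    return [c for c in cells if c.apical]


def count_marker(
    cells: Sequence[CellRecord],
    marker: str,
    roi_mask: Optional[BinaryMask3D] = None,
) -> int:
    """Count marker-positive cells whose centroid lies inside the ROI."""
    if marker not in ("gfap", "ki67"):
        raise ValueError("marker must be 'gfap' or 'ki67'")
    n = 0
    for c in cells:
        if not (c.gfap_pos if marker == "gfap" else c.ki67_pos):
            continue
        if roi_mask is not None:
            spacing = np.asarray(roi_mask.spacing, dtype=float)
            idx = np.round(c.centroid_um / spacing).astype(int)
            idx = np.clip(idx, 0, np.asarray(roi_mask.shape) - 1)
            if not roi_mask.data[tuple(idx)]:
                continue
        n += 1
    return n


def cells_table(cells: Sequence[CellRecord], sample_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "sample_id": sample_id,
            "cell_id": c.cell_id,
            "centroid_z_um": float(c.centroid_um[0]),
            "centroid_y_um": float(c.centroid_um[1]),
            "centroid_x_um": float(c.centroid_um[2]),
            "volume_um3": c.volume_um3,
            "apical_depth_um": c.apical_depth_um,
            "gfap_fraction": c.gfap_fraction,
            "gfap_pos": c.gfap_pos,
            "ki67_pos": c.ki67_pos,
            "apical": c.apical,
            "min_vessel_distance_um": c.min_vessel_distance_um,
        }
        for c in cells
    ]
    columns = [
        "sample_id",
        "cell_id",
        "centroid_z_um",
        "centroid_y_um",
        "centroid_x_um",
        "volume_um3",
        "apical_depth_um",
        "gfap_fraction",
        "gfap_pos",
        "ki67_pos",
        "apical",
        "min_vessel_distance_um",
    ]
    return pd.DataFrame(rows, columns=columns)
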