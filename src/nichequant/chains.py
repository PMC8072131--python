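"""Neuroblast-chain objects: extraction, eccentricity and density.

Eccentricity of a 3D object is one minus the ratio of its middle to its
maximal principal component: 1 for a line, 0 for a circle (or sphere).
By default the principal components are the standard deviations of the
um-scaled voxel cloud along its principal axes (square roots of the
covariance eigenvalues), which yields the intuitive semi-axis ratio for
ellipsoids; the raw-eigenvalue convention is available as a switch.  Both
conventions agree exactly on the line and circle anchor cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyMaskError
from .grids import BinaryMask3D
from .segmentation import label_components

__all__ = ["ChainObject", "extract_chains", "chain_eccentricity", "principal_components", "chain_density"]

_ECC_TIE_TOL = 1e-9  # relative eigenvalue floor / tie tolerance


@dataclass
class ChainObject:
    """One connected DCX+ component."""

    label: int
    voxels: np.ndarray  # (n, 3) integer indices (z, y, x)
    coords_um: np.ndarray  # (n, 3) um-scaled coordinates
    volume_um3: float
    pc_max: float
    pc_mid: float
    pc_min: float
    eccentricity: float  # NaN when undefined (all voxels coincident)

    @property
    def centroid_um(self) -> np.ndarray:
        return self.coords_um.mean(axis=0)


def principal_components(points_um: np.ndarray, convention: str = "sd") -> np.ndarray:
    """Sorted (descending) principal components of a 3D point cloud.

    ``sd``: square roots of covariance eigenvalues (standard deviations
    along principal axes); ``variance``: the eigenvalues themselves.
    Eigenvalues below ``1e-9`` of the largest are clamped to zero so exact
    degenerate shapes (lines, planes) come out exact.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) point cloud")
    if len(pts) < 1:
        raise ValueError("empty point cloud")
    cov = np.cov(pts.T, bias=True) if len(pts) > 1 else np.zeros((3, 3))
    eig = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    if eig[0] > 0:
        eig[eig < _ECC_TIE_TOL * eig[0]] = 0.0
    if convention == "sd":
        return np.sqrt(eig)
    if convention == "variance":
        return eig
    raise ValueError("convention must be 'sd' or 'variance'")


def chain_eccentricity(points_um: np.ndarray, convention: str = "sd") -> float:
    """1 - (middle / maximal principal component); in [0, 1], NaN if degenerate.

    Components equal within 1e-9 relative are treated as ties, so evenly
    spaced points on a circle give exactly 0 and collinear points exactly 1.
    """
    pcs = principal_components(points_um, convention=convention)
    if pcs[0] == 0.0:
        return float("nan")
    ecc = 1.0 - pcs[1] / pcs[0]
    if ecc < _ECC_TIE_TOL:
        ecc = 0.0
    return float(ecc)


def extract_chains(
    dcx_mask: BinaryMask3D,
    min_volume_um3: float = 0.0,
    convention: str = "sd",
) -> list[ChainObject]:
    """Connected components (26-connectivity) of the DCX mask above a volume cutoff."""
    labeled = label_components(dcx_mask, connectivity=26, min_size=0)
    voxvol = dcx_mask.voxel_volume_um3
    spacing = np.asarray(dcx_mask.spacing, dtype=float)
    out = []
    for lab in range(1, labeled.n_objects + 1):
        vox = np.argwhere(labeled.labels == lab)
        volume = len(vox) * voxvol
        if volume < min_volume_um3:
            continue
        coords = vox.astype(float) * spacing
        pcs = principal_components(coords, convention=convention)
        ecc = chain_eccentricity(coords, convention=convention)
        out.append(
            ChainObject(
                label=lab,
                voxels=vox,
                coords_um=coords,
                volume_um3=volume,
                pc_max=float(pcs[0]),
                pc_mid=float(pcs[1]),
                pc_min=float(pcs[2]),
                eccentricity=ecc,
            )
        )
    return out


def chain_density(
    dcx_mask: BinaryMask3D,
    niche_mask: BinaryMask3D,
    roi_mask: Optional[BinaryMask3D] = None,
) -> float:
    """DCX voxels / total niche voxels, optionally restricted to an ROI."""
    if not dcx_mask.same_geometry(niche_mask):
        raise ValueError("DCX and niche masks must share shape and spacing")
    roi = np.ones(dcx_mask.shape, dtype=bool) if roi_mask is None else roi_mask.data
    denom = int((niche_mask.data & roi).sum())
    if denom == 0:
        raise EmptyMaskError("niche mask is empty within the ROI")
    return int((dcx_mask.data & roi).sum()) / denom


def chains_table(chains: Sequence[ChainObject], sample_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "sample_id": sample_id,
            "chain_id": c.label,
            "volume_um3": c.volume_um3,
            "pc_max": c.pc_max,
            "pc_mid": c.pc_mid,
            "pc_min": c.pc_min,
            "eccentricity": c.eccentricity,
            "min_vessel_distance_um": np.nan,
        }
        for c in chains
    ]
    columns = [
        "sample_id",
        "chain_id",
        "volume_um3",
        "pc_max",
        "pc_mid",
        "pc_min",
        "eccentricity",
        "min_vessel_distance_um",
    ]
    return pd.DataFrame(rows, columns=columns)
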