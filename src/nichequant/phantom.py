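"""Synthetic niche phantoms with analytic ground truth.

The generator emulates the slab-shaped neurogenic niche as imaged in a
whole-mount: a tubular vessel plexus (laminin channel) with controllable
centreline shape and radius, nucleus blobs (DAPI) with optional GFAP halos
and Ki67 positivity placed at known apical depths and known distances from
the vessels, elongated chain objects (DCX channel) with known principal-axis
ratios, and 2D time-lapse movies whose cell counts follow a birth-death
process.  Every placement and every analytic quantity is recorded in a
:class:`PhantomTruth` so downstream estimators can be tested as
parameter-recovery problems.

Geometry is computed in micrometres in ``(x, y, z)`` coordinates and
rasterised onto the ``(z, y, x)``-ordered voxel grid; a voxel is foreground
iff its centre lies within the object (no antialiasing), which makes volume
fractions analytically predictable to voxelisation accuracy.  The ``z = 0``
face is the apical (ependymal) surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .exceptions import InvalidSpecError, PlacementError, SimulationError
from .grids import VoxelGrid3D
from .io import write_stack
from .timelapse import TimelapseMovie

__all__ = [
    "VesselSpec",
    "CellGroupSpec",
    "ChainGroupSpec",
    "NoiseSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_centerline",
    "polyline_arc_length",
    "polyline_tortuosity",
    "generate_niche_phantom",
    "simulate_birth_death_counts",
    "simulate_timelapse",
]

CENTERLINE_KINDS = ("straight", "sine", "helix", "arc")


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class VesselSpec:
    """One tubular vessel.

    The canonical centreline runs along +x starting at the origin (sine
    displacement in +y, helix in y/z, arc curving into +y); ``rotation``
    (a 3x3 matrix) and ``start_um`` (x, y, z) place it in the grid.  When
    ``start_um`` is None the tube is centred in the grid, and when
    ``length_um`` is None it spans the grid diagonal (the rasteriser clips
    to the grid, and truth quantities refer to the clipped part).
    """

    kind: str = "straight"
    radius_um: float = 3.0
    amplitude_um: float = 0.0
    wavelength_um: float = 0.0
    length_um: Optional[float] = None
    start_um: Optional[tuple[float, float, float]] = None
    rotation: Optional[tuple] = None  # 3x3, rows

    def __post_init__(self):
        if self.kind not in CENTERLINE_KINDS:
            raise InvalidSpecError(f"unknown centerline kind {self.kind!r}")
        if self.radius_um <= 0:
            raise InvalidSpecError("vessel radius must be positive")


@dataclass(frozen=True)
class CellGroupSpec:
    """A group of nucleus blobs sharing placement constraints."""

    count: int = 1
    nucleus_radius_um: float = 2.5
    depth_um: Optional[float] = None  # apical depth of the centroid; None = anywhere
    vessel_distance_um: Optional[float] = None  # centroid to nearest vessel voxel
    gfap: bool = False
    ki67: bool = False
    halo_um: float = 1.5  # GFAP halo thickness around the nucleus

    def __post_init__(self):
        if self.count < 0:
            raise InvalidSpecError("cell count must be non-negative")
        if self.nucleus_radius_um <= 0:
            raise InvalidSpecError("nucleus radius must be positive")


@dataclass(frozen=True)
class ChainGroupSpec:
    """A group of ellipsoidal chain objects (DCX channel)."""

    count: int = 1
    semi_axes_um: tuple[float, float, float] = (12.0, 4.0, 4.0)
    orientation: Optional[tuple[float, float, float]] = None  # major axis; None = random

    def __post_init__(self):
        if self.count < 0:
            raise InvalidSpecError("chain count must be non-negative")
        if any(a <= 0 for a in self.semi_axes_um):
            raise InvalidSpecError("chain semi-axes must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    sigma: float = 0.0
    background: float = 20.0
    foreground: float = 200.0

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidSpecError("noise sigma must be non-negative")
        if self.foreground <= self.background:
            raise InvalidSpecError("foreground intensity must exceed background")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic niche stack."""

    shape: tuple[int, int, int] = (32, 96, 96)  # (nz, ny, nx)
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (dz, dy, dx)
    vessels: tuple[VesselSpec, ...] = ()
    cells: tuple[CellGroupSpec, ...] = ()
    chains: tuple[ChainGroupSpec, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 4 for n in self.shape):
            raise InvalidSpecError(f"grid shape must be three sizes >= 4, got {self.shape}")
        sp = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in sp):
            raise InvalidSpecError("voxel spacing must be positive")
        finest = min(sp)
        for v in self.vessels:
            if v.radius_um < finest:
                raise InvalidSpecError(
                    f"vessel radius {v.radius_um} um below one voxel at finest spacing {finest} um"
                )
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_um", sp)
        object.__setattr__(self, "vessels", tuple(self.vessels))
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "chains", tuple(self.chains))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) spanned by voxel centres."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.spacing_um
        return ((nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz)


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom.

    Truth masks (``masks``) are the noiseless foreground used to rasterise
    each channel; re-measuring any truth quantity from the recorded
    geometry reproduces it exactly, and re-measuring from the rasterised
    masks reproduces it within voxelisation tolerance.
    """

    vessels: list = field(default_factory=list)  # per-vessel dicts
    vessel_volume_fraction: float = 0.0  # analytic (clipped cylinder volume / grid volume)
    vessel_voxel_fraction: float = 0.0  # from the rasterised mask
    cells: list = field(default_factory=list)
    chains: list = field(default_factory=list)
    expected_slope: Optional[float] = None
    expected_slope_linear: Optional[float] = None
    frame_counts: Optional[list] = None
    masks: dict = field(default_factory=dict)  # channel -> bool array (not serialised)
    spacing_um: tuple = (1.0, 1.0, 1.0)

    def to_json_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "vessels": clean(self.vessels),
            "vessel_volume_fraction": self.vessel_volume_fraction,
            "vessel_voxel_fraction": self.vessel_voxel_fraction,
            "cells": clean(self.cells),
            "chains": clean(self.chains),
            "expected_slope": self.expected_slope,
            "expected_slope_linear": self.expected_slope_linear,
            "frame_counts": clean(self.frame_counts),
            "spacing_um": list(self.spacing_um),
        }


# --------------------------------------------------------------------------
# centrelines


def make_centerline(
    kind: str,
    length_um: float,
    amplitude_um: float = 0.0,
    wavelength_um: float = 0.0,
    step_um: float = 0.5,
) -> np.ndarray:
    """Sample a canonical centreline as an ``(n, 3)`` polyline in um.

    ``length_um`` is the extent along the parameter axis (+x for straight,
    sine and helix; arc length along the curve for ``arc``, whose radius is
    ``amplitude_um``).  The polyline's numerically integrated arc length
    converges to the analytic arc length as ``step_um`` shrinks.
    """
    if kind not in CENTERLINE_KINDS:
        raise InvalidSpecError(f"unknown centerline kind {kind!r}")
    if not (length_um > 0) or not (step_um > 0):
        raise InvalidSpecError("length and step must be positive")
    if step_um > length_um / 10:
        raise InvalidSpecError("step must be at most length/10")
    if kind in ("sine", "helix"):
        if amplitude_um < 0 or wavelength_um <= 0:
            raise InvalidSpecError(f"{kind} needs amplitude >= 0 and wavelength > 0")
    if kind == "arc" and amplitude_um <= 0:
        raise InvalidSpecError("arc needs a positive radius (amplitude_um)")

    n = max(11, int(round(length_um / step_um)) + 1)
    t = np.linspace(0.0, length_um, n)
    if kind == "straight":
        pts = np.column_stack([t, np.zeros(n), np.zeros(n)])
    elif kind == "sine":
        y = amplitude_um * np.sin(2 * np.pi * t / wavelength_um)
        pts = np.column_stack([t, y, np.zeros(n)])
    elif kind == "helix":
        ph = 2 * np.pi * t / wavelength_um
        pts = np.column_stack([t, amplitude_um * np.cos(ph), amplitude_um * np.sin(ph)])
    else:  # arc: constant-speed parametrisation, curving from +x into +y
        r = amplitude_um
        th = t / r
        pts = np.column_stack([r * np.sin(th), r * (1 - np.cos(th)), np.zeros(n)])
    return pts


def polyline_arc_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def polyline_tortuosity(points: np.ndarray) -> float:
    """Arc length over chord length of an open polyline (>= 1)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise InvalidSpecError("tortuosity needs at least two points")
    chord = float(np.linalg.norm(points[-1] - points[0]))
    if chord == 0:
        return float("nan")
    return polyline_arc_length(points) / chord


# --------------------------------------------------------------------------
# rasterisation helpers


def _voxel_centers_um(shape, spacing):
    """Meshgrid-free voxel-centre coordinates per axis (z, y, x order)."""
    nz, ny, nx = shape
    dz, dy, dx = spacing
    return np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx


def _rotation_from_spec(rotation) -> np.ndarray:
    if rotation is None:
        return np.eye(3)
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise InvalidSpecError("rotation must be a 3x3 orthonormal matrix")
    return R


def _vessel_polyline_um(vspec: VesselSpec, spec: PhantomSpec):
    """Placed (world-frame) centreline polyline in (x, y, z) um, plus its step."""
    ex, ey, ez = spec.extent_um
    length = vspec.length_um
    if length is None:
        length = 1.2 * float(np.linalg.norm([ex, ey, ez]))
    step = min(spec.spacing_um) / 2.0
    step = min(step, length / 20.0)
    pts = make_centerline(vspec.kind, length, vspec.amplitude_um, vspec.wavelength_um, step)
    R = _rotation_from_spec(vspec.rotation)
    pts = pts @ R.T
    if vspec.start_um is None:
        center = np.array([ex / 2, ey / 2, ez / 2])
        pts = pts - pts.mean(axis=0) + center
    else:
        pts = pts + np.asarray(vspec.start_um, dtype=float)
    return pts, step


def _clip_polyline(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    ex, ey, ez = spec.extent_um
    lo = np.zeros(3)
    hi = np.array([ex, ey, ez])
    inside = np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
    if not inside.any():
        return pts[:0]
    # keep the longest contiguous inside run (tubes may exit and re-enter)
    runs, start = [], None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(inside)))
    s, e = max(runs, key=lambda r: r[1] - r[0])
    return pts[s:e]


def _rasterize_tube(
    pts_um: np.ndarray, radius_um: float, spec: PhantomSpec, step_um: float = 0.0
) -> np.ndarray:
    """Mark voxels whose centre lies within ``radius_um`` of the centreline.

    Distances are taken to the sampled polyline; compensating the radius by
    the half-step sampling error keeps voxels lying exactly on the tube
    surface (common on integer lattices) inside the tube, matching the
    continuous voxel-centre-in-tube rule.
    """
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing_um
    out = np.zeros(spec.shape, dtype=bool)
    if len(pts_um) == 0:
        return out
    radius_um = float(np.sqrt(radius_um**2 + (step_um / 2.0) ** 2))
    tree = cKDTree(pts_um)
    pad = radius_um + max(spec.spacing_um)
    lo = pts_um.min(axis=0) - pad
    hi = pts_um.max(axis=0) + pad
    ix0, ix1 = max(0, int(np.floor(lo[0] / dx))), min(nx - 1, int(np.ceil(hi[0] / dx)))
    iy0, iy1 = max(0, int(np.floor(lo[1] / dy))), min(ny - 1, int(np.ceil(hi[1] / dy)))
    iz0, iz1 = max(0, int(np.floor(lo[2] / dz))), min(nz - 1, int(np.ceil(hi[2] / dz)))
    if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
        return out
    zz, yy, xx = np.meshgrid(
        np.arange(iz0, iz1 + 1) * dz,
        np.arange(iy0, iy1 + 1) * dy,
        np.arange(ix0, ix1 + 1) * dx,
        indexing="ij",
    )
    q = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    d, _ = tree.query(q, workers=1)
    box = (d <= radius_um).reshape(zz.shape)
    out[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1] = box
    return out


def _rasterize_ball(center_um, radius_um, spec: PhantomSpec) -> np.ndarray:
    """Sphere given centre in (x, y, z) um."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing_um
    cx, cy, cz = center_um
    out = np.zeros(spec.shape, dtype=bool)
    ix0, ix1 = max(0, int(np.floor((cx - radius_um) / dx))), min(nx - 1, int(np.ceil((cx + radius_um) / dx)))
    iy0, iy1 = max(0, int(np.floor((cy - radius_um) / dy))), min(ny - 1, int(np.ceil((cy + radius_um) / dy)))
    iz0, iz1 = max(0, int(np.floor((cz - radius_um) / dz))), min(nz - 1, int(np.ceil((cz + radius_um) / dz)))
    if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
        return out
    zz, yy, xx = np.meshgrid(
        np.arange(iz0, iz1 + 1) * dz - cz,
        np.arange(iy0, iy1 + 1) * dy - cy,
        np.arange(ix0, ix1 + 1) * dx - cx,
        indexing="ij",
    )
    out[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1] = xx**2 + yy**2 + zz**2 <= radius_um**2
    return out


def _rasterize_ellipsoid(center_um, semi_axes_um, R: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Ellipsoid with principal semi-axes along the columns of ``R``."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing_um
    a = float(max(semi_axes_um))
    cx, cy, cz = center_um
    ix0, ix1 = max(0, int(np.floor((cx - a) / dx))), min(nx - 1, int(np.ceil((cx + a) / dx)))
    iy0, iy1 = max(0, int(np.floor((cy - a) / dy))), min(ny - 1, int(np.ceil((cy + a) / dy)))
    iz0, iz1 = max(0, int(np.floor((cz - a) / dz))), min(nz - 1, int(np.ceil((cz + a) / dz)))
    out = np.zeros(spec.shape, dtype=bool)
    if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
        return out
    zz, yy, xx = np.meshgrid(
        np.arange(iz0, iz1 + 1) * dz - cz,
        np.arange(iy0, iy1 + 1) * dy - cy,
        np.arange(ix0, ix1 + 1) * dx - cx,
        indexing="ij",
    )
    p = np.stack([xx, yy, zz], axis=-1) @ R  # project onto principal axes
    u = p / np.asarray(semi_axes_um, dtype=float)
    out[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1] = (u**2).sum(axis=-1) <= 1.0
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rotation_aligning_x(direction) -> np.ndarray:
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    # Gram-Schmidt a frame with first column v
    other = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(v, other)
    u /= np.linalg.norm(u)
    w = np.cross(v, u)
    return np.column_stack([v, u, w])


# --------------------------------------------------------------------------
# the generator


def generate_niche_phantom(spec: PhantomSpec):
    """Rasterise a phantom and return ``(channels, truth)``.

    ``channels`` maps ``laminin/dcx/gfap/ki67/dapi`` to intensity grids
    (two-level plus optional Gaussian noise, clipped at zero); ``truth``
    records analytic tortuosity, radii, volume fractions, placements and
    the noiseless masks.  A fixed seed fixes every output byte.
    """
    rng_place, rng_chain, rng_noise = [
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    ]
    dz, dy, dx = spec.spacing_um
    half_diag = 0.5 * float(np.linalg.norm(spec.spacing_um))
    grid_volume = float(np.prod(spec.shape)) * float(np.prod(spec.spacing_um))

    truth = PhantomTruth(spacing_um=spec.spacing_um)

    vessel_mask = np.zeros(spec.shape, dtype=bool)
    analytic_volume = 0.0
    for vspec in spec.vessels:
        polyline, step = _vessel_polyline_um(vspec, spec)
        pts = _clip_polyline(polyline, spec)
        if len(pts) < 2:
            raise PlacementError(f"vessel {vspec} lies outside the grid")
        vessel_mask |= _rasterize_tube(pts, vspec.radius_um, spec, step_um=step)
        arc = polyline_arc_length(pts)
        analytic_volume += np.pi * vspec.radius_um**2 * arc
        truth.vessels.append(
            {
                "kind": vspec.kind,
                "radius_um": vspec.radius_um,
                "arc_length_um": arc,
                "tortuosity": polyline_tortuosity(pts),
                "centerline_um_xyz": pts[:: max(1, len(pts) // 200)],
            }
        )
    truth.vessel_volume_fraction = analytic_volume / grid_volume
    truth.vessel_voxel_fraction = float(vessel_mask.mean())

    # distance field used to honour requested vessel distances (um)
    if vessel_mask.any():
        vessel_dist = ndimage.distance_transform_edt(~vessel_mask, sampling=spec.spacing_um)
    else:
        vessel_dist = None

    zs, ys, xs = _voxel_centers_um(spec.shape, spec.spacing_um)
    dapi_mask = np.zeros(spec.shape, dtype=bool)
    gfap_mask = np.zeros(spec.shape, dtype=bool)
    ki67_mask = np.zeros(spec.shape, dtype=bool)
    placed_centers: list[tuple[np.ndarray, float]] = []

    for gspec in spec.cells:
        for _ in range(gspec.count):
            ok_depth = np.ones(spec.shape, dtype=bool)
            if gspec.depth_um is not None:
                band = np.abs(zs - gspec.depth_um) <= dz / 2 + 1e-9
                ok_depth &= band[:, None, None]
            ok_dist = np.ones(spec.shape, dtype=bool)
            if gspec.vessel_distance_um is not None:
                if vessel_dist is None:
                    raise PlacementError(
                        f"cell group {gspec} requests a vessel distance but the phantom has no vessels"
                    )
                ok_dist = np.abs(vessel_dist - gspec.vessel_distance_um) <= half_diag
            candidates = np.argwhere(ok_depth & ok_dist & ~vessel_mask)
            r = gspec.nucleus_radius_um
            # keep nucleus inside the grid and away from already-placed nuclei
            ex, ey, ez = spec.extent_um
            sel = None
            order = rng_place.permutation(len(candidates))
            for idx in order:
                iz, iy, ix = candidates[idx]
                c = np.array([ix * dx, iy * dy, iz * dz])  # (x, y, z) um
                if not (
                    r <= c[0] <= ex - r
                    and r <= c[1] <= ey - r
                    and (gspec.depth_um is not None or r <= c[2] <= ez - r)
                ):
                    continue
                if all(
                    np.linalg.norm(c - pc) >= r + pr + 2.0 for pc, pr in placed_centers
                ):
                    sel = (c, (iz, iy, ix))
                    break
            if sel is None:
                raise PlacementError(f"could not place a cell from group {gspec}")
            c, (iz, iy, ix) = sel
            placed_centers.append((c, r))
            ball = _rasterize_ball(c, r, spec)
            dapi_mask |= ball
            if gspec.gfap:
                gfap_mask |= _rasterize_ball(c, r + gspec.halo_um, spec)
            if gspec.ki67:
                ki67_mask |= ball
            truth.cells.append(
                {
                    "center_um_zyx": [c[2], c[1], c[0]],
                    "radius_um": r,
                    "depth_um": float(c[2]),
                    "vessel_distance_um": float(vessel_dist[iz, iy, ix])
                    if vessel_dist is not None
                    else None,
                    "gfap": gspec.gfap,
                    "ki67": gspec.ki67,
                }
            )

    dcx_mask = np.zeros(spec.shape, dtype=bool)
    placed_chains: list[tuple[np.ndarray, float]] = []
    for cspec in spec.chains:
        axes = np.sort(np.asarray(cspec.semi_axes_um, dtype=float))[::-1]
        a = float(axes[0])
        ex, ey, ez = spec.extent_um
        if 2 * a > min(ex, ey, ez):
            raise PlacementError(f"chain group {cspec} does not fit in the grid")
        for _ in range(cspec.count):
            if cspec.orientation is not None:
                R = _rotation_aligning_x(cspec.orientation)
            else:
                R = _random_rotation(rng_chain)
            placed = False
            for _try in range(2000):
                c = np.array(
                    [
                        rng_chain.uniform(a, ex - a),
                        rng_chain.uniform(a, ey - a),
                        rng_chain.uniform(a, ez - a),
                    ]
                )
                if all(np.linalg.norm(c - pc) >= a + pa + 2.0 for pc, pa in placed_chains):
                    placed = True
                    break
            if not placed:
                raise PlacementError(f"could not place a chain from group {cspec}")
            placed_chains.append((c, a))
            dcx_mask |= _rasterize_ellipsoid(c, axes, R, spec)
            truth.chains.append(
                {
                    "center_um_zyx": [c[2], c[1], c[0]],
                    "semi_axes_um": axes.tolist(),
                    "pc_ratio_mid_max": float(axes[1] / axes[0]),
                    "eccentricity": float(1.0 - axes[1] / axes[0]),
                }
            )

    truth.masks = {
        "laminin": vessel_mask,
        "dcx": dcx_mask,
        "gfap": gfap_mask,
        "ki67": ki67_mask,
        "dapi": dapi_mask,
    }

    noise = spec.noise
    channels = {}
    for name, mask in truth.masks.items():
        img = np.where(mask, noise.foreground, noise.background).astype(np.float32)
        if noise.sigma > 0:
            img = img + rng_noise.normal(0.0, noise.sigma, size=img.shape).astype(np.float32)
            img = np.clip(img, 0.0, None)
        channels[name] = VoxelGrid3D(img, spec.spacing_um, channel=name)
    return channels, truth


def write_phantom(channels: dict, truth: PhantomTruth, out_dir) -> Path:
    """Persist a generated phantom: one TIFF+sidecar per channel plus truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, grid in channels.items():
        write_stack(grid, out_dir / f"{name}.tif")
    (out_dir / "truth.json").write_text(json.dumps(truth.to_json_dict(), sort_keys=True))
    return out_dir


# --------------------------------------------------------------------------
# time-lapse simulation


def _ols_slope(y: np.ndarray) -> float:
    x = np.arange(len(y), dtype=float)
    x = x - x.mean()
    denom = float((x**2).sum())
    return float((x * (np.asarray(y, dtype=float) - np.mean(y))).sum() / denom)


def simulate_birth_death_counts(
    n_initial: int,
    p_division: float,
    p_death: float,
    n_frames: int,
    seed=None,
    births_per_frame: Optional[int] = None,
) -> np.ndarray:
    """Per-frame population counts of the branching process.

    Each frame, every cell independently divides with probability
    ``p_division`` or dies with probability ``p_death``.  With
    ``births_per_frame`` set the process is deterministic: exactly that
    many cells are added per frame.
    """
    if not (0 <= p_division <= 1 and 0 <= p_death <= 1 and p_division + p_death <= 1):
        raise InvalidSpecError("division/death probabilities must lie in [0, 1] and sum to <= 1")
    if n_frames < 2:
        raise InvalidSpecError("need at least 2 frames")
    if n_initial < 0:
        raise InvalidSpecError("initial count must be non-negative")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_frames, dtype=int)
    n = int(n_initial)
    counts[0] = n
    for t in range(1, n_frames):
        if births_per_frame is not None:
            n = n + births_per_frame
        elif n > 0:
            # each cell draws one fate: divide, die, or persist
            births, deaths, _ = rng.multinomial(
                n, [p_division, p_death, 1.0 - p_division - p_death]
            )
            n = n + int(births) - int(deaths)
        counts[t] = n
    return counts


def expected_timelapse_slope(
    n_initial: int, p_division: float, p_death: float, n_frames: int
) -> float:
    """OLS slope of the exact mean trajectory ``n0 * (1 + p_div - p_death)^t``.

    The fitted slope is a linear statistic of the counts, so its
    expectation equals this value exactly; for small ``(p_div - p_death) *
    n_frames`` it reduces to the linear-regime rate ``n0 * (p_div -
    p_death)`` per frame.
    """
    m = 1.0 + p_division - p_death
    mean_traj = n_initial * m ** np.arange(n_frames)
    return _ols_slope(mean_traj)


def _render_frame(positions, shape, radius_px, bg, fg, sigma, rng) -> np.ndarray:
    h, w = shape
    img = np.full((h, w), bg, dtype=np.float32)
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx) in positions:
        sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        img[sel] = fg
    if sigma > 0:
        img = np.clip(img + rng.normal(0, sigma, img.shape).astype(np.float32), 0, None)
    return img


def simulate_timelapse(
    n_initial: int = 100,
    p_division: float = 0.01,
    p_death: float = 0.005,
    n_frames: int = 980,
    interval_min: float = 5.0,
    seed=None,
    births_per_frame: Optional[int] = None,
    frame_shape: tuple[int, int] = (192, 192),
    cell_radius_px: int = 3,
    noise_sigma: float = 0.0,
    background: float = 20.0,
    foreground: float = 200.0,
):
    """Simulate a movie of disk-shaped cells and return ``(movie, truth)``.

    Defaults mirror the acquisition protocol the package targets (980
    frames at 5-minute intervals).  Cells are rendered as non-overlapping
    disks; if a frame cannot accommodate its population the simulation
    raises :class:`SimulationError`.
    """
    seq = np.random.SeedSequence(seed if seed is not None else 0)
    s_counts, s_pos, s_noise = seq.spawn(3)
    counts = simulate_birth_death_counts(
        n_initial, p_division, p_death, n_frames, seed=s_counts, births_per_frame=births_per_frame
    )
    rng_pos = np.random.default_rng(s_pos)
    rng_noise = np.random.default_rng(s_noise)
    h, w = frame_shape
    min_sep = 2 * cell_radius_px + 2

    def place_new(existing):
        for _ in range(5000):
            cy = rng_pos.uniform(cell_radius_px + 1, h - cell_radius_px - 1)
            cx = rng_pos.uniform(cell_radius_px + 1, w - cell_radius_px - 1)
            if all((cy - ey) ** 2 + (cx - ex) ** 2 >= min_sep**2 for ey, ex in existing):
                return (cy, cx)
        raise SimulationError("field of view overcrowded; could not place a new cell")

    positions: list[tuple[float, float]] = []
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for t in range(n_frames):
        target = int(counts[t])
        while len(positions) > target:
            positions.pop(rng_pos.integers(len(positions)))
        while len(positions) < target:
            positions.append(place_new(positions))
        frames[t] = _render_frame(
            positions, frame_shape, cell_radius_px, background, foreground, noise_sigma, rng_noise
        )

    movie = TimelapseMovie(frames, interval_min=interval_min)
    truth = PhantomTruth(
        frame_counts=counts.tolist(),
        expected_slope=(
            float(births_per_frame)
            if births_per_frame is not None
            else expected_timelapse_slope(n_initial, p_division, p_death, n_frames)
        ),
        expected_slope_linear=(
            float(births_per_frame)
            if births_per_frame is not None
            else n_initial * (p_division - p_death)
        ),
    )
    return movie, truth
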