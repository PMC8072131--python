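import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nichequant import BinaryMask3D, PhantomSpec, VesselSpec, generate_niche_phantom


@pytest.fixture(scope="session")
def straight_tube_phantom():
    """Straight 3 um-radius tube along x in an isotropic 1 um grid."""
    spec = PhantomSpec(
        shape=(41, 41, 100),
        spacing_um=(1.0, 1.0, 1.0),
        vessels=(VesselSpec(kind="straight", radius_um=3.0),),
        seed=11,
    )
    channels, truth = generate_niche_phantom(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def straight_tube_mask(straight_tube_phantom):
    spec, _, truth = straight_tube_phantom
    return BinaryMask3D(truth.masks["laminin"], spec.spacing_um, channel="laminin")


def brute_force_distance_map(mask: np.ndarray, spacing) -> np.ndarray:
    """Independent oracle: per-voxel minimum Euclidean distance to any
    foreground voxel, computed by explicit min-over-voxels search."""
    sp = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask) * sp
    out = np.empty(mask.shape, dtype=float)
    all_idx = np.argwhere(np.ones(mask.shape, dtype=bool))
    pts = all_idx * sp
    for start in range(0, len(pts), 4000):
        chunk = pts[start : start + 4000]
        d2 = ((chunk[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2)
        out.ravel()[start : start + 4000] = np.sqrt(d2.min(axis=1))
    return out
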