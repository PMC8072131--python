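"""Validated analysis parameters.

All thresholds used downstream live here with their defaults: the 5 um
apical cutoff for stem-cell classification, the 10 um capillary diameter
cutoff, the nucleus/GFAP overlap fraction, minimum object sizes, and the
segmentation knobs.  Unknown keys are rejected rather than ignored so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .exceptions import ConfigError

__all__ = ["AnalysisConfig", "read_pipeline_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    # cell classification
    apical_threshold_um: float = 5.0
    gfap_overlap_fraction: float = 0.3
    ki67_overlap_fraction: float = 0.3
    nucleus_min_volume_um3: float = 20.0
    nucleus_max_volume_um3: float = 2000.0
    # vessels
    capillary_max_diameter_um: float = 10.0
    spur_prune_factor: float = 2.0
    diameter_weighting: str = "per-branch"
    # segmentation
    threshold_method: str = "otsu"
    fixed_threshold: Optional[float] = None
    smoothing_sigma_um: float = 0.5
    opening_radius_um: float = 0.0
    min_component_voxels: int = 8
    connectivity: int = 26
    niche_closing_radius_um: float = 5.0
    # chains
    min_chain_volume_um3: float = 50.0
    eccentricity_convention: str = "sd"
    # proximity
    cell_distance_mode: str = "surface"
    # timelapse
    timelapse_interval_min: float = 5.0
    timelapse_min_area_px: int = 5
    # statistics
    posthoc_method: str = "sidak"

    def __post_init__(self):
        def positive(name):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or v <= 0:
                raise ConfigError(f"{name} must be a positive number, got {v!r}")

        def nonneg(name):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or v < 0:
                raise ConfigError(f"{name} must be a non-negative number, got {v!r}")

        for name in (
            "apical_threshold_um",
            "capillary_max_diameter_um",
            "nucleus_min_volume_um3",
            "nucleus_max_volume_um3",
            "niche_closing_radius_um",
            "min_chain_volume_um3",
            "timelapse_interval_min",
        ):
            positive(name)
        for name in ("smoothing_sigma_um", "opening_radius_um", "spur_prune_factor"):
            nonneg(name)
        for name, hi in (("gfap_overlap_fraction", 1.0), ("ki67_overlap_fraction", 1.0)):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not 0 <= v <= hi:
                raise ConfigError(f"{name} must lie in [0, {hi}], got {v!r}")
        if self.connectivity not in (6, 26):
            raise ConfigError(f"connectivity must be 6 or 26, got {self.connectivity!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("threshold_method 'fixed' requires fixed_threshold")
        if self.eccentricity_convention not in ("sd", "variance"):
            raise ConfigError("eccentricity_convention must be 'sd' or 'variance'")
        if self.cell_distance_mode not in ("surface", "centroid"):
            raise ConfigError("cell_distance_mode must be 'surface' or 'centroid'")
        if self.diameter_weighting not in ("per-branch", "per-voxel"):
            raise ConfigError("diameter_weighting must be 'per-branch' or 'per-voxel'")
        if self.posthoc_method not in ("sidak", "tukey"):
            raise ConfigError("posthoc_method must be 'sidak' or 'tukey'")
        if not isinstance(self.min_component_voxels, int) or self.min_component_voxels < 0:
            raise ConfigError("min_component_voxels must be a non-negative integer")
        if not isinstance(self.timelapse_min_area_px, int) or self.timelapse_min_area_px < 0:
            raise ConfigError("timelapse_min_area_px must be a non-negative integer")


_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def read_pipeline_config(source) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a JSON/YAML file or a mapping.

    An empty document yields the full default set; unknown keys and
    out-of-range values raise :class:`ConfigError`.
    """
    if source is None:
        doc: Mapping = {}
    elif isinstance(source, AnalysisConfig):
        return source
    elif isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text) if text.strip() else {}
        if doc is None:
            doc = {}
        if not isinstance(doc, Mapping):
            raise ConfigError(f"config document must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return AnalysisConfig(**doc)
    except TypeError as exc:  # e.g. non-keyword-able values
        raise ConfigError(str(exc)) from exc
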