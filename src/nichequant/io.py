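"""Stack, mask, table and metadata I/O.

Stacks travel as plain multi-page TIFF (pages = z) with a JSON sidecar
carrying ``spacing_um`` (``[dz, dy, dx]``) and the channel label; spacing is
never embedded in TIFF tags.  Tables are CSV with a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import MissingSpacingError, RaggedPagesError, SchemaError
from .grids import BinaryMask3D, VoxelGrid3D

__all__ = [
    "SampleMeta",
    "sidecar_path",
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_metrics_table",
    "read_metrics_table",
]


@dataclass(frozen=True)
class SampleMeta:
    """Factor labels attached to one imaged sample."""

    sample_id: str
    sex: str
    age_group: str
    roi: str = "whole"

    SEXES = ("male", "female")
    ROIS = ("whole", "anterior")

    def __post_init__(self):
        if self.sex not in self.SEXES:
            raise ValueError(f"sex must be one of {self.SEXES}, got {self.sex!r}")
        if self.roi not in self.ROIS:
            raise ValueError(f"roi must be one of {self.ROIS}, got {self.roi!r}")


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(grid: VoxelGrid3D, path) -> Path:
    """Write a grid as multi-page TIFF plus a JSON spacing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(grid.data), photometric="minisblack")
    meta = {"spacing_um": list(grid.spacing), "channel": grid.channel}
    sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))
    return path


def read_stack(path, spacing=None, channel=None) -> VoxelGrid3D:
    """Read a multi-page TIFF into a :class:`VoxelGrid3D`.

    Spacing comes from the JSON sidecar unless overridden explicitly; a
    stack without any spacing source is an error, never a silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise RaggedPagesError(f"{path}: pages have differing shapes {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    side = sidecar_path(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    if spacing is None:
        spacing = meta.get("spacing_um")
    if spacing is None:
        raise MissingSpacingError(f"{path}: no sidecar spacing and no explicit override")
    if channel is None:
        channel = meta.get("channel", path.stem)
    return VoxelGrid3D(data, tuple(spacing), channel=channel)


def write_mask(mask: BinaryMask3D, path) -> Path:
    """Persist a binary mask as 8-bit TIFF (0/255) plus sidecar."""
    grid = VoxelGrid3D(mask.data.astype(np.uint8) * 255, mask.spacing, channel=mask.channel)
    return write_stack(grid, path)


def read_mask(path, spacing=None, channel=None) -> BinaryMask3D:
    grid = read_stack(path, spacing=spacing, channel=channel)
    return BinaryMask3D(grid.data > 0, grid.spacing, channel=grid.channel)


def write_metrics_table(records, path) -> Path:
    """Write per-object or per-sample measurements as CSV.

    ``records`` is a DataFrame or an iterable of mappings that must share
    one schema; an empty record list yields a header-only file only when a
    DataFrame (which carries its columns) is passed.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            keys = list(records[0].keys())
            for r in records[1:]:
                if list(r.keys()) != keys:
                    raise SchemaError(f"mixed schemas: {keys} vs {list(r.keys())}")
            df = pd.DataFrame.from_records(records, columns=keys)
        else:
            df = pd.DataFrame()
    # default float formatting is the shortest round-trip repr: exact read-back
    df.to_csv(path, index=False)
    return path


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_sample_table(samples: Sequence[SampleMeta], path) -> Path:
    return write_metrics_table(
        [
            {"sample_id": s.sample_id, "sex": s.sex, "age_group": s.age_group, "roi": s.roi}
            for s in samples
        ],
        path,
    )
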