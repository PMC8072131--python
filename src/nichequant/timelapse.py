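"""Per-frame cell counting and the population-slope statistic.

The population slope is the ordinary-least-squares slope of cell count
versus frame index — a robust summary of net proliferation (divisions
minus deaths) over a movie.  Frame-to-frame identity tracking is not
needed for this statistic; counts suffice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import InvalidSpecError

__all__ = ["TimelapseMovie", "PopulationSlope", "count_cells_per_frame", "population_slope"]


@dataclass(frozen=True)
class TimelapseMovie:
    """Ordered 2D frames captured at a fixed interval (minutes)."""

    frames: np.ndarray  # (t, h, w)
    interval_min: float = 5.0

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise InvalidSpecError("a movie needs >= 2 frames of identical shape")
        if self.interval_min <= 0:
            raise InvalidSpecError("capture interval must be positive")
        frames = frames.copy()
        frames.setflags(write=False)
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class PopulationSlope:
    slope_per_frame: float
    slope_per_hour: float
    intercept: float
    r_squared: float
    n_frames: int


def count_cells_per_frame(
    movie: TimelapseMovie,
    fixed_threshold: float | None = None,
    min_area_px: int = 5,
):
    """Segment each frame (threshold + minimum-area components) and count.

    Returns ``(counts, flags)``; a constant (unsegmentable) frame gets
    count 0 and its quality flag set.  Components use 8-connectivity.
    """
    counts = np.zeros(movie.n_frames, dtype=int)
    flags = np.zeros(movie.n_frames, dtype=bool)
    structure = np.ones((3, 3), dtype=bool)
    for t in range(movie.n_frames):
        frame = movie.frames[t]
        if fixed_threshold is not None:
            thr = fixed_threshold
        else:
            if np.ptp(frame) == 0:
                flags[t] = True
                continue
            thr = threshold_otsu(frame)
        fg = frame > thr
        labels, n = ndimage.label(fg, structure=structure)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            counts[t] = int((sizes >= min_area_px).sum())
    return counts, flags


def population_slope(counts, interval_min: float = 5.0) -> PopulationSlope:
    """OLS line fit of count versus frame index.

    ``slope_per_hour = slope_per_frame * 60 / interval_min``.  R-squared of
    a zero-variance series is 0 by convention.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise InvalidSpecError("population slope needs at least 2 counts")
    if interval_min <= 0:
        raise InvalidSpecError("interval must be positive")
    x = np.arange(len(y), dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float((xc**2).sum())
    slope = float((xc * yc).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    sst = float((yc**2).sum())
    if sst == 0:
        r2 = 0.0
    else:
        ssr = float(((y - (intercept + slope * x)) ** 2).sum())
        r2 = 1.0 - ssr / sst
    return PopulationSlope(
        slope_per_frame=slope,
        slope_per_hour=slope * 60.0 / interval_min,
        intercept=intercept,
        r_squared=r2,
        n_frames=len(y),
    )
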