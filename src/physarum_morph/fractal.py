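"""Box-counting fractal dimension of segmented network masks.

Network complexity is summarised per timepoint by the box-counting
dimension D: cover the foreground with grids of boxes of side s, count the
occupied boxes N(s), and take D = −slope of the least-squares line through
(log s, log N(s)).  Line-like patterns give D ≈ 1, space-filling ones
D ≈ 2.  The analysis runs on the growth-segmentation masks subsampled to
one frame every 10 minutes.

Grids for the dimension estimate are anchored at the foreground bounding
box, which makes D invariant to translating the mask or padding it with
background.  Box sizes default to descending powers of two between 2 px and
a quarter of the smaller bounding-box side; the fit R² is reported so poor
scaling regimes are visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imaging_io import ValidationError

__all__ = ["FractalSeries", "box_count", "fractal_dimension",
           "fractal_series", "default_box_sizes"]


@dataclass
class FractalSeries:
    """Fractal dimension over time (sampled every ``every_minutes``)."""

    times_h: np.ndarray
    dimension: np.ndarray
    fit_r2: np.ndarray
    box_sizes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.dimension < -1e-9) or np.any(self.dimension > 2 + 1e-9):
            raise ValidationError("2-D box dimension must lie in [0, 2]")
        if len(self.box_sizes) < 2 or np.any(np.diff(self.box_sizes) >= 0):
            raise ValidationError("box sizes must be >=2 strictly decreasing")


def box_count(mask: np.ndarray, box_size: int) -> int:
    """Number of origin-anchored ``box_size``² grid cells touching foreground.

    An empty mask yields 0.
    """
    if box_size < 1:
        raise ValidationError("box_size must be >= 1")
    mask = np.asarray(mask, bool)
    if not mask.any():
        return 0
    h, w = mask.shape
    ph = (-h) % box_size
    pw = (-w) % box_size
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)))
    H, W = mask.shape
    blocks = mask.reshape(H // box_size, box_size, W // box_size, box_size)
    return int(blocks.any(axis=(1, 3)).sum())


def default_box_sizes(shape: tuple[int, int]) -> np.ndarray:
    """Descending powers of 2 in [2, min(shape)/4] (at least three sizes)."""
    upper = max(min(shape) // 4, 8)
    sizes = []
    s = 2
    while s <= upper:
        sizes.append(s)
        s *= 2
    return np.array(sorted(sizes, reverse=True), int)


def fractal_dimension(
    mask: np.ndarray, box_sizes: np.ndarray | None = None
) -> tuple[float, float]:
    """Box-counting dimension D and the R² of the log–log fit.

    The mask is cropped to its foreground bounding box before counting, so
    the estimate does not depend on where the pattern sits in the raster.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValidationError("fractal dimension undefined for empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cropped = mask[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    if box_sizes is None:
        box_sizes = default_box_sizes(cropped.shape)
    box_sizes = np.asarray(box_sizes, int)
    if box_sizes.size < 3:
        raise ValidationError("need >= 3 box sizes for a stable fit")
    counts = np.array([box_count(cropped, int(s)) for s in box_sizes], float)
    res = stats.linregress(np.log(box_sizes), np.log(counts))
    return float(-res.slope), float(res.rvalue**2)


def fractal_series(
    masks: list[np.ndarray],
    times_s: np.ndarray,
    every_minutes: float = 10.0,
    box_sizes: np.ndarray | None = None,
) -> FractalSeries:
    """D over time on masks subsampled to a regular 10-min grid.

    For each grid point (t = 0 inclusive, up to the last timestamp) the
    temporally nearest mask is used.
    """
    times_s = np.asarray(times_s, float)
    if len(masks) == 0 or len(masks) != len(times_s):
        raise ValidationError("need a non-empty, aligned mask series")
    step = every_minutes * 60.0
    grid = np.arange(0.0, times_s[-1] + 1e-9, step)
    if grid.size == 0:
        raise ValidationError("empty temporal subsample")
    dims, r2s, used_sizes = [], [], None
    for t in grid:
        idx = int(np.argmin(np.abs(times_s - t)))
        m = masks[idx]
        if used_sizes is None:
            used_sizes = (box_sizes if box_sizes is not None
                          else default_box_sizes(np.asarray(m).shape))
        d, r2 = fractal_dimension(m, used_sizes)
        dims.append(d)
        r2s.append(r2)
    return FractalSeries(
        times_h=grid / 3600.0,
        dimension=np.asarray(dims),
        fit_r2=np.asarray(r2s),
        box_sizes=np.asarray(used_sizes, int),
    )
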