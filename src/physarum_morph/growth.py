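"""Segmentation, area/exploration time series and dose–response quantities.

The organism appears as a dark branching network on bright agar.  Each
masked, denoised frame is binarised with an inverse local-mean adaptive
threshold (Gaussian-weighted window, default 71 px, offset 4 intensity
units): a pixel is foreground iff it is darker than its local weighted mean
minus the offset.  Foreground pixel counts, converted through the metric
calibration, give the covered area A_t in mm²; the cumulative union of all
foreground pixels up to time t gives the explored area EA_t, which separates
locomotion from net growth.

Derived scalars follow the printed formulas:

* growth rate       = (A_t24 − A_t0) / A_t0          (dimensionless)
* exploration rate  = EA_t24 / 24                    (mm² h⁻¹)
* growth inhibition = (Area_c − mean Area_c0) / mean Area_c0

the last being the normalised difference in covered area at compound
concentration c relative to the untreated control; its negation is the
(positive) inhibition magnitude when the treatment shrinks the organism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_local

from .imaging_io import FrameSeries, ScaleCalibration, ValidationError

__all__ = [
    "SegmentationParams",
    "AreaSeries",
    "ExplorationSeries",
    "segment_network",
    "segment_series",
    "area_series",
    "growth_rate",
    "exploration_series",
    "exploration_rate",
    "growth_inhibition",
    "fit_dose_response",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Adaptive-threshold settings for the growth segmentation.

    ``window`` is the local-mean neighbourhood (odd, default 71 px);
    ``offset`` is subtracted from the Gaussian-weighted local mean before
    the inverse comparison (default 4 intensity units).
    """

    window: int = 71
    offset: float = 4.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")


@dataclass
class AreaSeries:
    """Covered area per timepoint, raw and baseline-subtracted.

    ``area_mm2`` holds the raw covered area; ``area_norm_mm2`` subtracts the
    t₀ value (used for plotting growth increments; the growth-rate formula
    uses raw areas).
    """

    times_h: np.ndarray
    area_mm2: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.area_mm2 = np.asarray(self.area_mm2, float)
        if self.area_mm2.size == 0:
            raise ValidationError("empty area series")
        if np.any(self.area_mm2 < 0):
            raise ValidationError("areas must be non-negative")

    @property
    def area_norm_mm2(self) -> np.ndarray:
        return self.area_mm2 - self.area_mm2[0]

    @property
    def a_t0(self) -> float:
        return float(self.area_mm2[0])

    def area_at(self, t_h: float, tol_h: float | None = None) -> float:
        """Raw area at the frame nearest ``t_h`` hours.

        ``tol_h`` bounds the allowed distance (default: one capture
        interval).
        """
        idx = int(np.argmin(np.abs(self.times_h - t_h)))
        if tol_h is None:
            dt = np.diff(self.times_h)
            tol_h = float(dt.min()) if dt.size else np.inf
        if abs(self.times_h[idx] - t_h) > tol_h + 1e-9:
            raise ValidationError(
                f"no frame within {tol_h:.3g} h of t = {t_h} h"
            )
        return float(self.area_mm2[idx])


@dataclass
class ExplorationSeries:
    """Cumulative explored area EA_t (union of all occupied pixels)."""

    times_h: np.ndarray
    explored_mm2: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.explored_mm2 = np.asarray(self.explored_mm2, float)
        if np.any(np.diff(self.explored_mm2) < -1e-9):
            raise ValidationError("explored area must be non-decreasing")

    def explored_at(self, t_h: float) -> float:
        idx = int(np.argmin(np.abs(self.times_h - t_h)))
        return float(self.explored_mm2[idx])


def segment_network(
    frame: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    roi_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binarise one masked, denoised frame: dark organism on bright agar.

    Foreground iff intensity < (Gaussian-weighted local mean over
    ``params.window``) − ``params.offset``; output restricted to ``roi_mask``
    when given.
    """
    frame = np.asarray(frame, float)
    if frame.ndim != 2:
        raise ValidationError("segment_network expects a 2-D frame")
    thresh = threshold_local(
        frame, block_size=params.window, method="gaussian",
        offset=params.offset,
    )
    fg = frame < thresh
    if roi_mask is not None:
        fg &= np.asarray(roi_mask, bool)
    return fg


def segment_series(
    series: FrameSeries,
    params: SegmentationParams = SegmentationParams(),
    roi_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Segment every frame of a series with shared parameters."""
    return [segment_network(f, params, roi_mask) for f in series.frames]


def _mm2_per_px(cal: ScaleCalibration) -> float:
    return (cal.pixel_pitch / 1000.0) ** 2


def area_series(
    masks: list[np.ndarray],
    cal: ScaleCalibration,
    times_s: np.ndarray,
    condition_label: str = "",
) -> AreaSeries:
    """Covered area per timepoint from foreground pixel counts."""
    if len(masks) == 0:
        raise ValidationError("empty mask series")
    if len(masks) != len(times_s):
        raise ValidationError("one timestamp per mask required")
    px_area = _mm2_per_px(cal)
    counts = np.array([int(np.count_nonzero(m)) for m in masks], float)
    return AreaSeries(
        times_h=np.asarray(times_s, float) / 3600.0,
        area_mm2=counts * px_area,
        condition_label=condition_label,
    )


def growth_rate(series: AreaSeries, horizon_h: float = 24.0) -> float:
    """Relative area increase over the observation horizon.

    (A_t24 − A_t0) / A_t0, using raw areas; A_t24 is the frame nearest
    24 h within one capture interval.
    """
    if series.times_h[-1] < horizon_h - 1e-9:
        raise ValidationError(
            f"series spans {series.times_h[-1]:.2f} h < {horizon_h} h"
        )
    a0 = series.a_t0
    if a0 <= 0:
        raise ValidationError("growth rate undefined: A_t0 = 0")
    a24 = series.area_at(horizon_h)
    return (a24 - a0) / a0


def exploration_series(
    masks: list[np.ndarray],
    cal: ScaleCalibration,
    times_s: np.ndarray,
) -> ExplorationSeries:
    """Cumulative union of occupied pixels, converted to mm²."""
    if len(masks) == 0:
        raise ValidationError("empty mask series")
    px_area = _mm2_per_px(cal)
    union = np.zeros_like(np.asarray(masks[0], bool))
    explored = np.empty(len(masks))
    for i, m in enumerate(masks):
        union |= np.asarray(m, bool)
        explored[i] = union.sum()
    return ExplorationSeries(
        times_h=np.asarray(times_s, float) / 3600.0,
        explored_mm2=explored * px_area,
    )


def exploration_rate(
    series: ExplorationSeries, horizon_h: float = 24.0
) -> float:
    """EA_t24 / 24: mean explored area per hour over the horizon (mm²/h)."""
    if series.times_h[-1] < horizon_h - 1e-9:
        raise ValidationError(
            f"series spans {series.times_h[-1]:.2f} h < {horizon_h} h"
        )
    return series.explored_at(horizon_h) / horizon_h


def growth_inhibition(
    treated_areas: np.ndarray | float,
    control_areas: np.ndarray,
) -> np.ndarray:
    """Normalised area difference relative to the untreated control.

    Returns (Area_c − mean(Area_c0)) / mean(Area_c0) per treated replicate —
    negative under inhibition.  Negate for a positive inhibition magnitude.
    """
    control = np.atleast_1d(np.asarray(control_areas, float))
    if control.size == 0 or control.mean() <= 0:
        raise ValidationError("need >=1 control replicate with positive mean")
    ref = control.mean()
    treated = np.atleast_1d(np.asarray(treated_areas, float))
    return (treated - ref) / ref


@dataclass
class DoseResponseFit:
    """Polynomial dose–response summary (inhibition vs concentration)."""

    coefficients: np.ndarray  # highest degree first (np.polyfit order)
    degree: int
    concentrations: np.ndarray
    mean_inhibition: np.ndarray
    sd_inhibition: np.ndarray
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, c: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(c, float))


def fit_dose_response(
    concentrations: np.ndarray,
    inhibitions: np.ndarray,
    degree: int = 3,
) -> DoseResponseFit:
    """Least-squares polynomial fit of per-replicate inhibition vs dose.

    ``concentrations`` and ``inhibitions`` are parallel per-replicate
    arrays (a concentration may repeat across replicates).  Requires at
    least ``degree + 1`` distinct concentrations.
    """
    c = np.asarray(concentrations, float)
    y = np.asarray(inhibitions, float)
    if c.shape != y.shape:
        raise ValidationError("concentrations and inhibitions must align")
    uniq = np.unique(c)
    if uniq.size < degree + 1:
        raise ValidationError(
            f"need >= {degree + 1} distinct concentrations, got {uniq.size}"
        )
    coeffs = np.polyfit(c, y, degree)
    resid = y - np.polyval(coeffs, c)
    means = np.array([y[c == u].mean() for u in uniq])
    sds = np.array([y[c == u].std(ddof=0) for u in uniq])
    return DoseResponseFit(
        coefficients=coeffs, degree=degree, concentrations=uniq,
        mean_inhibition=means, sd_inhibition=sds, residuals=resid,
    )
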