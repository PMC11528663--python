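"""Loading, denoising, scale calibration and Petri-dish ROI detection.

Time-lapse recordings of *Physarum polycephalum* arrive as ordered series of
still frames, captured either every 60 s for 24 h (growth set) or every 4 s
for 1 h (vein-contraction set).  This module turns files on disk into a
calibrated :class:`FrameSeries`, removes sensor noise with non-local-means
filtering, converts a known physical reference length into a pixel pitch,
and locates the circular inner rim of the Petri dish so that everything
outside the growth region can be excluded from analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
from skimage import feature, restoration, transform

__all__ = [
    "FrameSeries",
    "ScaleCalibration",
    "ROIMask",
    "load_frame_series",
    "to_grayscale",
    "denoise_frame",
    "calibrate_scale",
    "detect_dish_roi",
    "apply_roi",
]

#: Luminance weights used to collapse RGB frames to grey (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])

#: Default fill for pixels outside the dish ROI.  Bright, so the
#: inverse-binary adaptive threshold never marks masked-out pixels as
#: organism foreground.
BACKGROUND_FILL = 255


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class DetectionError(RuntimeError):
    """Automatic structure detection failed; manual input is advised."""


@dataclass
class FrameSeries:
    """An ordered, dimensionally consistent stack of 8-bit grey frames.

    Parameters
    ----------
    frames:
        List of 2-D ``uint8`` arrays, all the same shape.
    timestamps:
        Seconds from the first frame; strictly increasing.
    pixel_pitch:
        Physical size of one pixel in µm, or ``None`` until calibrated.
    source_paths:
        Provenance strings (file paths or phantom descriptions).
    """

    frames: list[np.ndarray]
    timestamps: np.ndarray
    pixel_pitch: float | None = None
    source_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValidationError("FrameSeries requires at least one frame")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValidationError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValidationError(f"frame {i} is not 2-D greyscale")
            if f.shape != shape:
                raise ValidationError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass(frozen=True)
class ScaleCalibration:
    """Metric calibration: physical size of one pixel.

    ``pixel_pitch`` is in µm per pixel and must be finite and positive.
    """

    pixel_pitch: float
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_pitch) or self.pixel_pitch <= 0:
            raise ValidationError("pixel_pitch must be finite and positive")

    @property
    def mm_per_px(self) -> float:
        return self.pixel_pitch / 1000.0

    def px_to_mm(self, px: float) -> float:
        return px * self.pixel_pitch / 1000.0

    def mm_to_px(self, mm: float) -> float:
        return mm * 1000.0 / self.pixel_pitch


@dataclass
class ROIMask:
    """Circular region of interest covering the inner area of the dish."""

    center: tuple[float, float]  # (row, col)
    radius: float  # px
    mask: np.ndarray  # boolean, True inside the circle

    def __post_init__(self) -> None:
        r, (cy, cx) = self.radius, self.center
        h, w = self.mask.shape
        fully_inside = (r <= cy <= h - 1 - r) and (r <= cx <= w - 1 - r)
        if fully_inside and r > 0:
            area = float(self.mask.sum())
            expected = np.pi * r**2
            # rasterized disc area must track the analytic one
            if abs(area - expected) / expected > 0.01:
                raise ValidationError(
                    "mask area inconsistent with radius "
                    f"({area:.0f} px vs π·r² = {expected:.0f} px)"
                )


def _circle_mask(shape: tuple[int, int], center: tuple[float, float],
                 radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to 8-bit grey with luminance weighting."""
    if frame.ndim == 2:
        out = frame
    elif frame.ndim == 3 and frame.shape[2] in (3, 4):
        out = frame[..., :3].astype(float) @ _LUMA
    else:
        raise ValidationError(f"unsupported frame shape {frame.shape}")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def load_frame_series(
    paths: Sequence[str | Path],
    interval_s: float,
    pixel_pitch: float | None = None,
) -> FrameSeries:
    """Read an ordered list of PNG/TIFF files into a :class:`FrameSeries`.

    Timestamps are ``index × interval_s`` — derived from the configured
    capture cadence, never from file modification times, so reruns are
    reproducible.  All frames must share the same dimensions; RGB input is
    converted to grey.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("no input frames given")
    frames = []
    for p in paths:
        try:
            raw = iio.imread(p)
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read image file: {p}") from exc
        frames.append(to_grayscale(np.asarray(raw)))
    ts = np.arange(len(frames), dtype=float) * float(interval_s)
    return FrameSeries(frames, ts, pixel_pitch=pixel_pitch,
                       source_paths=[str(p) for p in paths])


def load_manifest(manifest_csv: str | Path) -> tuple[list[Path], np.ndarray]:
    """Read an explicit frame manifest (columns ``path,t_seconds``)."""
    paths, times = [], []
    base = Path(manifest_csv).parent
    with open(manifest_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            p = Path(row["path"])
            paths.append(p if p.is_absolute() else base / p)
            times.append(float(row["t_seconds"]))
    return paths, np.asarray(times)


def denoise_frame(
    frame: np.ndarray,
    strength: float = 8.0,
    template_window: int = 5,
    search_window: int = 21,
) -> np.ndarray:
    """Non-local-means denoising of an 8-bit grey frame.

    Parameters mirror the acquisition pipeline's defaults: filter strength 8,
    5-px patch (template) window, 21-px search window.  Output has the same
    dtype, shape and intensity range as the input.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValidationError("denoise_frame expects a 2-D greyscale frame")
    if template_window % 2 == 0 or template_window < 1:
        raise ValidationError("template_window must be odd and positive")
    if strength <= 0:
        return frame.copy()
    img = frame.astype(float) / 255.0
    # search_window is a full width; skimage takes a centre-to-edge distance
    patch_distance = max((int(search_window) - 1) // 2, 1)
    out = restoration.denoise_nl_means(
        img,
        h=strength / 255.0,
        patch_size=int(template_window),
        patch_distance=patch_distance,
        fast_mode=True,
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def calibrate_scale(
    known_length_px: float, known_length_mm: float, source: str = "reference"
) -> ScaleCalibration:
    """Derive µm-per-pixel from a reference object of known physical size."""
    if known_length_px <= 0 or known_length_mm <= 0:
        raise ValidationError("calibration lengths must be positive")
    pitch = 1000.0 * known_length_mm / known_length_px
    return ScaleCalibration(pixel_pitch=pitch, source=source)


def detect_dish_roi(
    frame: np.ndarray,
    min_radius: int,
    max_radius: int,
    min_dist: int | None = None,
    radius_step: int = 1,
    canny_sigma: float = 2.0,
    min_accumulator: float = 0.3,
) -> ROIMask:
    """Locate the circular dish rim by a Hough circle transform.

    Edge pixels (Canny) vote for circle centres over candidate radii
    spanning ``[min_radius, max_radius]`` in steps of ``radius_step``
    (1 px by default — a coarser grid dilutes the votes of circles whose
    radius falls between grid values).  ``min_dist`` is accepted for API
    parity with multi-circle setups but only one dish is ever returned.

    Raises
    ------
    DetectionError
        If no circle in the radius bounds reaches ``min_accumulator``
        support; callers should fall back to a manually specified ROI.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValidationError("detect_dish_roi expects a greyscale frame")
    if not (0 < min_radius < max_radius):
        raise ValidationError("need 0 < min_radius < max_radius")
    edges = feature.canny(frame.astype(float) / 255.0, sigma=canny_sigma)
    if not edges.any():
        raise DetectionError(
            "no edges found — blank frame? Supply a manual ROI."
        )
    radii = np.arange(min_radius, max_radius + 1, max(int(radius_step), 1))
    hough = transform.hough_circle(edges, radii)
    accums, cxs, cys, rads = transform.hough_circle_peaks(
        hough, radii, total_num_peaks=5, normalize=True
    )
    if len(accums) == 0 or accums[0] < min_accumulator:
        raise DetectionError(
            "no circular rim detected within the radius bounds "
            f"[{min_radius}, {max_radius}] — supply a manual ROI."
        )
    # Highest vote wins; ties (within 2 %) broken by distance to the
    # frame centre.
    fc = np.array([frame.shape[0] / 2, frame.shape[1] / 2])
    near = [k for k in range(len(accums)) if accums[k] >= accums[0] * 0.98]
    best = min(near, key=lambda k: np.hypot(cys[k] - fc[0], cxs[k] - fc[1]))
    center = (float(cys[best]), float(cxs[best]))
    # The rim ring has two concentric edges (agar→rim and rim→exterior)
    # whose Hough votes are near-tied; the ROI is the *inner* circle of
    # the dish, so the radius is refined from the radial histogram of
    # edge pixels around the chosen centre, taking the innermost ring
    # with at least half the support of the strongest one.
    ys, xs = np.nonzero(edges)
    dist = np.hypot(ys - center[0], xs - center[1])
    bins = np.arange(min_radius - 2, max_radius + 3)
    hist, _ = np.histogram(dist, bins=bins)
    smooth = np.convolve(hist, [1.0, 2.0, 1.0], mode="same")
    strong = np.flatnonzero(smooth >= 0.5 * smooth.max())
    first = strong[0]
    in_ring = (dist >= bins[first] - 1.5) & (dist <= bins[first] + 2.5)
    radius = float(dist[in_ring].mean())
    return ROIMask(center=center, radius=radius,
                   mask=_circle_mask(frame.shape, center, radius))


def manual_roi(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> ROIMask:
    """Build an ROI directly from a known centre and radius."""
    return ROIMask(center=center, radius=radius,
                   mask=_circle_mask(shape, center, radius))


def apply_roi(
    frame: np.ndarray,
    roi: ROIMask | np.ndarray,
    fill: int = BACKGROUND_FILL,
) -> np.ndarray:
    """Blank everything outside the ROI with a bright background value.

    ``roi`` may be a detected :class:`ROIMask` or any boolean raster of the
    same shape (True = keep).
    """
    frame = np.asarray(frame)
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, bool)
    if frame.shape != mask.shape:
        raise ValidationError(
            f"frame shape {frame.shape} != ROI shape {mask.shape}"
        )
    out = frame.copy()
    out[~mask] = fill
    return out
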