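"""Vein-diameter morphometry: section detection, width rays and QC cascade.

The vein set (1 frame every 4 s for an hour) images the plasmodial network
at high magnification.  The first frame is binarised with an inverse
adaptive threshold (window 69–91 px, offset 2), thinned to a one-pixel
skeleton, and straight skeleton stretches are found with a probabilistic
Hough line transform (threshold 25 votes, minimum line length 10 px).  Each
detected segment becomes a *section* carrying at least four measurement
positions; at every position a ray is cast along the segment normal in both
directions until the background intensity is reached, and the traversed
distance — converted through the pixel pitch — is the local vein width.

Sections then pass a five-stage quality-control cascade, in order:

1. initial size   — mean first-frame width over 1 mm → rejected (not a vein)
2. consistency    — positions outside 1.5×IQR of the section's widths are
                    dropped; fewer than 4 survivors → rejected
3. median         — section median > 2× the median of all sections' medians
                    → rejected
4. contrast       — vein and local background intensities closer than a
                    minimum contrast → rejected
5. overlap        — of two geometrically overlapping sections the one with
                    more positions survives (ties: lower id)

Surviving sections are measured at fixed image coordinates in every frame
of the hour, yielding one width-vs-time trace per position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import morphology, transform

from .imaging_io import FrameSeries, ScaleCalibration, ValidationError

__all__ = [
    "VeinSection",
    "DiameterTrace",
    "skeletonize",
    "detect_sections",
    "measure_width",
    "qc_initial_size",
    "qc_positional_consistency",
    "qc_median_comparison",
    "qc_colour_gradient",
    "qc_overlap",
    "qc_cascade",
    "track_sections",
]

#: Default adaptive-threshold window for the vein set: midpoint of the
#: 69–91 px range used at full sensor resolution.
VEIN_WINDOW_DEFAULT = 79
VEIN_OFFSET_DEFAULT = 2.0


@dataclass
class VeinSection:
    """A straight measurement site on the vein skeleton.

    ``detection_line`` holds the segment endpoints in (row, col) pixels;
    ``measurement_positions`` are >= 4 equally spaced points on it, each
    with the (shared) unit normal in ``normals``.  ``status`` is ``active``
    or ``rejected``; a rejected section keeps its ``reject_reason``.
    """

    section_id: int
    detection_line: tuple[tuple[float, float], tuple[float, float]]
    measurement_positions: np.ndarray  # (n, 2) rows of (row, col)
    normals: np.ndarray  # (n, 2) unit vectors
    status: str = "active"
    reject_reason: str = ""
    position_active: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.measurement_positions = np.asarray(
            self.measurement_positions, float
        )
        self.normals = np.asarray(self.normals, float)
        if self.position_active.size == 0:
            self.position_active = np.ones(
                len(self.measurement_positions), bool
            )
        if self.status == "active" and self.n_active < 4:
            raise ValidationError(
                "an active section needs >= 4 measurement positions"
            )
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise ValidationError("normals must be unit vectors")
        d = np.subtract(*self.detection_line)
        d = d / np.linalg.norm(d)
        # perpendicular within 1 degree
        if np.any(np.abs(self.normals @ d) > math.sin(math.radians(1))):
            raise ValidationError("normals must be perpendicular to the line")

    @property
    def n_active(self) -> int:
        return int(self.position_active.sum())

    @property
    def active_positions(self) -> np.ndarray:
        return self.measurement_positions[self.position_active]

    def reject(self, reason: str) -> "VeinSection":
        return replace(self, status="rejected", reject_reason=reason)


@dataclass
class DiameterTrace:
    """Width-vs-time signal of one measurement position (µm)."""

    section_id: int
    position_index: int
    times_s: np.ndarray
    width_um: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.width_um = np.asarray(self.width_um, float)
        if self.times_s.shape != self.width_um.shape:
            raise ValidationError("times and widths must align")
        if np.any(self.width_um < 0):
            raise ValidationError("widths must be non-negative")

    @property
    def mean_width_um(self) -> float:
        return float(self.width_um.mean())


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary vein mask to an 8-connected one-pixel-wide skeleton.

    Iterative morphological thinning (Zhang–Suen style); preserves the
    topology of the mask.  An empty mask yields an empty skeleton.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros_like(mask)
    return morphology.skeletonize(mask)


def _positions_on_line(
    p0: np.ndarray, p1: np.ndarray, spacing_px: float = 5.0,
    min_positions: int = 4,
) -> np.ndarray:
    """Equally spaced points on a segment: every ~5 skeleton px, >= 4."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(min_positions, int(length // spacing_px) + 1)
    t = np.linspace(0.0, 1.0, n)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def detect_sections(
    skeleton: np.ndarray,
    threshold: int = 25,
    min_line_length: int = 10,
    line_gap: int = 3,
    spacing_px: float = 5.0,
    seed: int = 0,
) -> list[VeinSection]:
    """Find straight measurement sections on the skeleton.

    Probabilistic Hough transform with 1-px rho and 1° theta resolution;
    each accepted segment is populated with equally spaced measurement
    positions and the shared unit normal.  Returns an empty list when the
    skeleton carries no line-like structure.
    """
    skeleton = np.asarray(skeleton, bool)
    if not skeleton.any():
        return []
    lines = transform.probabilistic_hough_line(
        skeleton,
        threshold=threshold,
        line_length=min_line_length,
        line_gap=line_gap,
        rng=seed,
    )
    sections: list[VeinSection] = []
    for sid, ((c0, r0), (c1, r1)) in enumerate(lines):
        p0 = np.array([r0, c0], float)
        p1 = np.array([r1, c1], float)
        d = p1 - p0
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d /= norm
        normal = np.array([-d[1], d[0]])
        pos = _positions_on_line(p0, p1, spacing_px)
        sections.append(
            VeinSection(
                section_id=sid,
                detection_line=(tuple(p0), tuple(p1)),
                measurement_positions=pos,
                normals=np.tile(normal, (len(pos), 1)),
            )
        )
    return sections


def _bilinear(frame: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Sample a float frame at fractional (row, col) points."""
    h, w = frame.shape
    r = np.clip(pts[:, 0], 0, h - 1.001)
    c = np.clip(pts[:, 1], 0, w - 1.001)
    r0, c0 = np.floor(r).astype(int), np.floor(c).astype(int)
    fr, fc = r - r0, c - c0
    return (
        frame[r0, c0] * (1 - fr) * (1 - fc)
        + frame[r0 + 1, c0] * fr * (1 - fc)
        + frame[r0, c0 + 1] * (1 - fr) * fc
        + frame[r0 + 1, c0 + 1] * fr * fc
    )


#: Angular fan (radians) around the nominal normal over which the minimum
#: chord is taken.  A Hough line slightly oblique to the vein axis inflates
#: the normal chord by 1/cos of the misalignment; the perpendicular width
#: is the minimum chord through the position, so probing a small fan around
#: the nominal normal removes the obliquity bias.
ANGLE_FAN = (0.0, 0.15, -0.15, 0.3, -0.3)


def _ray_chord(frame: np.ndarray, position: np.ndarray, direction: np.ndarray,
               stop_intensity: float, max_steps: int, step_px: float) -> float:
    """Chord length (px) through ``position`` along ±direction."""
    steps = np.arange(1, max_steps + 1) * step_px
    chord = 0.0
    for sign in (+1.0, -1.0):
        pts = position[None, :] + sign * steps[:, None] * direction[None, :]
        vals = _bilinear(frame, pts)
        beyond = np.flatnonzero(vals > stop_intensity)
        chord += steps[beyond[0]] if beyond.size else steps[-1]
    return chord


def measure_width(
    frame: np.ndarray,
    position: np.ndarray,
    normal: np.ndarray,
    stop_intensity: float,
    pixel_pitch: float,
    max_steps: int = 200,
    step_px: float = 0.25,
    angle_fan: tuple[float, ...] = ANGLE_FAN,
) -> float:
    """Vein width at one position by ray casting along the normal (µm).

    From ``position`` the ray extends along +normal and −normal in
    ``step_px`` increments until the interpolated intensity exceeds
    ``stop_intensity`` (the vein/background decision level); the summed
    traversed distance times the pixel pitch is the width.  The chord is
    additionally evaluated over a small angular fan around the nominal
    normal and the minimum taken, which corrects for detection lines that
    are slightly oblique to the vein axis.  A position already on
    background returns 0 and is left to the QC cascade.
    """
    frame = np.asarray(frame, float)
    position = np.asarray(position, float)
    normal = np.asarray(normal, float)
    if _bilinear(frame, position[None, :])[0] > stop_intensity:
        return 0.0
    best = np.inf
    for ang in angle_fan:
        c, s = math.cos(ang), math.sin(ang)
        d = np.array([c * normal[0] - s * normal[1],
                      s * normal[0] + c * normal[1]])
        best = min(best, _ray_chord(frame, position, d, stop_intensity,
                                    max_steps, step_px))
    return best * pixel_pitch


def estimate_stop_intensity(
    frame: np.ndarray, section: VeinSection, probe_px: float = 15.0
) -> tuple[float, float, float]:
    """Vein/background decision level for one section.

    Returns ``(stop, vein_median, background_median)`` where ``stop`` is
    the midpoint between the median intensity on the section's measurement
    line and the local background median.  The background probe samples
    rings at 1–4 × ``probe_px`` along the normals and keeps the brightest
    median, so a probe distance that still falls inside a wide vein does
    not masquerade as background.
    """
    frame = np.asarray(frame, float)
    pos = section.measurement_positions
    vein = float(np.median(_bilinear(frame, pos)))
    background = -np.inf
    for mult in (1.0, 2.0, 3.0, 4.0):
        ring = np.concatenate([
            pos + mult * probe_px * section.normals,
            pos - mult * probe_px * section.normals,
        ])
        background = max(background, float(np.median(_bilinear(frame, ring))))
    return (vein + background) / 2.0, vein, background


def measure_section_widths(
    frame: np.ndarray,
    section: VeinSection,
    pixel_pitch: float,
    stop_intensity: float | None = None,
) -> np.ndarray:
    """Width at every (active) measurement position of a section (µm)."""
    if stop_intensity is None:
        stop_intensity, _, _ = estimate_stop_intensity(frame, section)
    return np.array([
        measure_width(frame, p, n, stop_intensity, pixel_pitch)
        for p, n in zip(section.measurement_positions, section.normals)
    ])


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def qc_initial_size(
    sections: list[VeinSection],
    first_frame_widths: list[np.ndarray],
    max_mean_width_um: float = 1000.0,
) -> list[VeinSection]:
    """Reject sections whose mean first-frame width exceeds 1 mm (strict >).

    Widths that large do not correspond to real veins (typically the dish
    rim or the inoculum blob).
    """
    out = []
    for sec, widths in zip(sections, first_frame_widths):
        if sec.status == "active" and \
                float(np.mean(widths[sec.position_active])) > max_mean_width_um:
            out.append(sec.reject("size"))
        else:
            out.append(sec)
    return out


def _iqr_bounds(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def qc_positional_consistency(
    sections: list[VeinSection],
    first_frame_widths: list[np.ndarray],
    min_positions: int = 4,
) -> list[VeinSection]:
    """Drop positions outside 1.5×IQR of the section's widths.

    Sections straddling vein intersections produce divergent per-position
    widths; outlying positions are removed, and a section keeping fewer
    than ``min_positions`` is rejected.
    """
    out = []
    for sec, widths in zip(sections, first_frame_widths):
        if sec.status != "active":
            out.append(sec)
            continue
        w = np.asarray(widths, float)
        lo, hi = _iqr_bounds(w[sec.position_active])
        keep = sec.position_active & (w >= lo) & (w <= hi)
        if keep.sum() < min_positions:
            out.append(sec.reject("consistency"))
        else:
            out.append(replace(sec, position_active=keep))
    return out


def qc_median_comparison(
    sections: list[VeinSection],
    first_frame_widths: list[np.ndarray],
    factor: float = 2.0,
) -> list[VeinSection]:
    """Reject sections whose median width is over ``factor``× the overall.

    The overall reference is the median of all active sections' medians
    (strict >).
    """
    medians = {}
    for sec, widths in zip(sections, first_frame_widths):
        if sec.status == "active":
            w = np.asarray(widths, float)
            medians[sec.section_id] = float(np.median(w[sec.position_active]))
    if len(medians) < 2:
        return list(sections)
    overall = float(np.median(list(medians.values())))
    out = []
    for sec in sections:
        if sec.status == "active" and medians[sec.section_id] > factor * overall:
            out.append(sec.reject("median"))
        else:
            out.append(sec)
    return out


def qc_colour_gradient(
    sections: list[VeinSection],
    frame: np.ndarray,
    contrast_min: float = 10.0,
) -> list[VeinSection]:
    """Reject sections that cannot tell vein from background.

    The median intensity on the measurement line is compared with the
    median of the local background ring; an absolute difference below
    ``contrast_min`` intensity units → rejected (strict <).
    """
    out = []
    for sec in sections:
        if sec.status != "active":
            out.append(sec)
            continue
        _, vein, background = estimate_stop_intensity(frame, sec)
        if abs(vein - background) < contrast_min:
            out.append(sec.reject("contrast"))
        else:
            out.append(sec)
    return out


def _footprints_intersect(a: VeinSection, b: VeinSection,
                          radius_px: float = 2.0) -> bool:
    """Do two sections' measurement-line footprints overlap?"""
    pa, pb = a.active_positions, b.active_positions
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return bool((d < 2 * radius_px).any()) or _segments_cross(
        a.detection_line, b.detection_line
    )


def _segments_cross(l1, l2) -> bool:
    (p, q), (r, s) = np.asarray(l1, float), np.asarray(l2, float)

    def orient(a, b, c):
        u, v = b - a, c - a
        return np.sign(u[0] * v[1] - u[1] * v[0])

    return (orient(p, q, r) * orient(p, q, s) < 0
            and orient(r, s, p) * orient(r, s, q) < 0)


def qc_overlap(sections: list[VeinSection]) -> list[VeinSection]:
    """Discard redundant overlapping sections.

    When two active sections overlap, the one with more active positions
    survives; on a tie the lower section id wins.
    """
    order = sorted(
        (s for s in sections if s.status == "active"),
        key=lambda s: (-s.n_active, s.section_id),
    )
    rejected: set[int] = set()
    for i, a in enumerate(order):
        if a.section_id in rejected:
            continue
        for b in order[i + 1:]:
            if b.section_id in rejected:
                continue
            if _footprints_intersect(a, b):
                rejected.add(b.section_id)
    return [
        s.reject("overlap")
        if s.status == "active" and s.section_id in rejected
        else s
        for s in sections
    ]


def qc_cascade(
    sections: list[VeinSection],
    first_frame: np.ndarray,
    pixel_pitch: float,
    max_mean_width_um: float = 1000.0,
    contrast_min: float = 10.0,
) -> tuple[list[VeinSection], list[np.ndarray]]:
    """Run the full five-stage cascade on first-frame measurements.

    Order: size → consistency → median → contrast → overlap.  Returns the
    updated sections and the first-frame per-position widths (µm) used by
    the filters.  Re-running the cascade on its own output is a no-op.
    """
    widths = [
        measure_section_widths(first_frame, s, pixel_pitch) for s in sections
    ]
    sections = qc_initial_size(sections, widths, max_mean_width_um)
    sections = qc_positional_consistency(sections, widths)
    sections = qc_median_comparison(sections, widths)
    sections = qc_colour_gradient(sections, first_frame, contrast_min)
    sections = qc_overlap(sections)
    return sections, widths


def track_sections(
    frames: FrameSeries,
    sections: list[VeinSection],
    cal: ScaleCalibration | None = None,
) -> list[DiameterTrace]:
    """Measure every active position in every frame of the vein set.

    Positions stay fixed in image coordinates across the hour; the stop
    intensity is re-estimated per frame so slow illumination drift does not
    bias the rays.  Returns one trace per (section, position).
    """
    pitch = cal.pixel_pitch if cal else frames.pixel_pitch
    if pitch is None:
        raise ValidationError("pixel pitch required (calibrate the series)")
    active = [s for s in sections if s.status == "active"]
    traces: list[DiameterTrace] = []
    buffers = {
        s.section_id: np.zeros((s.n_active, len(frames))) for s in active
    }
    for f_idx, frame in enumerate(frames.frames):
        frame = np.asarray(frame, float)
        for s in active:
            stop, _, _ = estimate_stop_intensity(frame, s)
            pos = s.measurement_positions[s.position_active]
            nrm = s.normals[s.position_active]
            for k, (p, n) in enumerate(zip(pos, nrm)):
                buffers[s.section_id][k, f_idx] = measure_width(
                    frame, p, n, stop, pitch
                )
    for s in active:
        pos_indices = np.flatnonzero(s.position_active)
        for k, pi in enumerate(pos_indices):
            traces.append(
                DiameterTrace(
                    section_id=s.section_id,
                    position_index=int(pi),
                    times_s=frames.timestamps,
                    width_um=buffers[s.section_id][k],
                )
            )
    return traces
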