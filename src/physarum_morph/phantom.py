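"""Seeded synthetic phantoms with exported ground truth.

Real recordings of *Physarum polycephalum* are large and condition-specific,
so every analytic stage in this package is validated against synthetic
phantom imagery whose geometry is known exactly: a bright agar field inside
a dark dish rim, dark discs of analytic area for the growth stage, random
branching stroke networks of controlled width for the morphometry stage,
sinusoidally width-modulated networks for the contraction stage, and exact
fractal rasters for the complexity stage.  Each generator is deterministic
for a fixed (spec, seed) pair and returns its ground truth alongside the
images, so oracles never have to re-read pixels.

Strokes are drawn from a signed distance field with a one-pixel
anti-aliasing ramp by default (realistic greyscale edges for the
width-measurement rays); a hard-edge mode exists for exact pixel-count
tests.  Noise is additive Gaussian clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .imaging_io import FrameSeries, ValidationError

__all__ = [
    "PhantomSpec",
    "make_dish",
    "make_growing_disk_series",
    "make_vein_network",
    "make_pulsating_series",
    "make_fractal_pattern",
]

AGAR = 220  # bright agar intensity
RIM = 40    # dark dish rim
VEIN = 60   # dark organism / vein intensity


@dataclass
class PhantomSpec:
    """Geometry, dynamics and noise of one synthetic phantom.

    ``kind`` selects the generator; units are pixels, seconds and Hz.
    Output is bit-identical for a fixed spec + seed.
    """

    kind: str = "dish"
    shape: tuple[int, int] = (512, 512)
    seed: int = 0
    pixel_pitch: float = 10.0  # µm per px
    noise_sigma: float = 0.0
    # dish
    rim_radius: float = 200.0
    rim_thickness: float = 6.0
    # growing / translating disk
    disk_radius0: float = 30.0
    disk_growth_px_per_frame: float = 0.0
    disk_velocity: tuple[float, float] = (0.0, 0.0)  # px/frame (row, col)
    n_frames: int = 25
    interval_s: float = 3600.0
    # vein network
    n_branches: int = 6
    stroke_width_px: float = 20.0
    stroke_widths_px: tuple[float, ...] | None = None
    layout: str = "tree"  # "tree" (connected) or "separated" (disjoint)
    flat_caps: bool = False  # truncate stroke ends (exact 2r·L area)
    antialias: bool = True
    # pulsation
    mod_frequency_hz: float = 0.010
    mod_amplitude: float = 0.2
    mod_phase: float = 0.0
    fs_hz: float = 0.25
    chirp_to_hz: float | None = None


def _noise(rng: np.random.Generator, img: np.ndarray,
           sigma: float) -> np.ndarray:
    if sigma <= 0:
        return img
    noisy = img.astype(float) + rng.normal(0.0, sigma, img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def make_dish(spec: PhantomSpec,
              center: tuple[float, float] | None = None
              ) -> tuple[np.ndarray, dict]:
    """Petri-dish frame: bright interior, dark rim ring, grey exterior.

    Returns the frame and ground truth ``{"center": (row, col),
    "radius": px}`` for the inner rim circle.
    """
    h, w = spec.shape
    if spec.rim_radius >= min(h, w) / 2:
        raise ValidationError("rim radius must fit inside the frame")
    if center is None:
        center = (h / 2.0, w / 2.0)
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.ogrid[:h, :w]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    img = np.full((h, w), 128, np.uint8)  # exterior
    img[dist < spec.rim_radius + spec.rim_thickness] = RIM
    img[dist < spec.rim_radius] = AGAR
    img = _noise(rng, img, spec.noise_sigma)
    return img, {"center": center, "radius": float(spec.rim_radius)}


def _disc(shape: tuple[int, int], center: tuple[float, float],
          radius: float, antialias: bool = True) -> np.ndarray:
    """Coverage map in [0,1] of a disc, AA ramp of one pixel."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    if antialias:
        return np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return (dist <= radius).astype(float)


def make_growing_disk_series(
    spec: PhantomSpec,
    center: tuple[float, float] | None = None,
) -> tuple[FrameSeries, dict]:
    """Dark disc of radius r(t) = r₀ + k·t on a bright field.

    An optional per-frame velocity translates the disc, turning the series
    into an exploration phantom.  Ground truth carries the per-frame
    centres, radii and analytic areas (πr², in px² and mm²).
    """
    h, w = spec.shape
    if center is None:
        center = (h / 2.0, w / 2.0)
    rng = np.random.default_rng(spec.seed)
    frames, centers, radii = [], [], []
    for t in range(spec.n_frames):
        r = spec.disk_radius0 + spec.disk_growth_px_per_frame * t
        c = (center[0] + spec.disk_velocity[0] * t,
             center[1] + spec.disk_velocity[1] * t)
        if r <= 0 or not (r < c[0] < h - r and r < c[1] < w - r):
            raise ValidationError("disc must stay inside the frame")
        cov = _disc((h, w), c, r, spec.antialias)
        img = np.clip(
            np.rint(AGAR - (AGAR - VEIN) * cov), 0, 255
        ).astype(np.uint8)
        frames.append(_noise(rng, img, spec.noise_sigma))
        centers.append(c)
        radii.append(r)
    ts = np.arange(spec.n_frames) * spec.interval_s
    series = FrameSeries(frames, ts, pixel_pitch=spec.pixel_pitch,
                         source_paths=[f"phantom:disk:{spec.seed}:{i}"
                                       for i in range(spec.n_frames)])
    radii_arr = np.asarray(radii)
    mm2 = (spec.pixel_pitch / 1000.0) ** 2
    truth = {
        "centers": np.asarray(centers),
        "radii_px": radii_arr,
        "area_px2": np.pi * radii_arr**2,
        "area_mm2": np.pi * radii_arr**2 * mm2,
    }
    return series, truth


def _random_tree_segments(
    rng: np.random.Generator, shape: tuple[int, int], n_branches: int,
    margin: float | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random tree of straight segments, grown node by node."""
    h, w = shape
    if margin is None:
        margin = min(40.0, 0.12 * min(h, w))
    nodes = [np.array([h / 2.0, w / 2.0])]
    segments = []
    for _ in range(n_branches):
        base = nodes[rng.integers(len(nodes))]
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.18, 0.32) * min(h, w)
        tip = base + length * np.array([np.sin(ang), np.cos(ang)])
        tip = np.clip(tip, margin, [h - margin, w - margin])
        if np.linalg.norm(tip - base) < 20:
            continue
        segments.append((base.copy(), tip))
        nodes.append(tip)
    return segments


def _separated_segments(
    rng: np.random.Generator, shape: tuple[int, int], n_strokes: int,
    max_width_px: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint near-horizontal strokes, one per horizontal band.

    Bands are tall enough that strokes of up to ``max_width_px`` never
    touch, so per-edge geometry (width, length, projected area 2r·L)
    stays exact — the layout used by width- and volume-recovery oracles.
    """
    h, w = shape
    band = h / n_strokes
    if band < max_width_px + 12:
        raise ValidationError(
            "canvas too small for the requested stroke count/width"
        )
    segments = []
    for k in range(n_strokes):
        y = (k + 0.5) * band
        margin = max_width_px / 2 + 4
        x0 = rng.uniform(margin, 0.25 * w)
        x1 = rng.uniform(0.75 * w, w - margin)
        slope_room = (band - max_width_px - 8) / 2
        dy = rng.uniform(-slope_room, slope_room)
        segments.append((np.array([y - dy, x0]), np.array([y + dy, x1])))
    return segments


def _stroke_coverage(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray,
                     width_px: float, antialias: bool,
                     flat_caps: bool = False) -> np.ndarray:
    """Coverage in [0,1] of a thick stroke (segment dilated by width/2).

    Round caps by default (capsule); ``flat_caps`` truncates the stroke at
    the segment endpoints so its projected area is exactly width × length,
    which the volume-identity oracle relies on.
    """
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    pts = np.stack([rr, cc], axis=-1).astype(float)
    d = p1 - p0
    L2 = float(d @ d)
    t_raw = ((pts - p0) @ d) / L2 if L2 > 0 else np.zeros(shape)
    t = np.clip(t_raw, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    dist = np.linalg.norm(pts - proj, axis=-1)
    half = width_px / 2.0
    if antialias:
        cov = np.clip(half + 0.5 - dist, 0.0, 1.0)
    else:
        cov = (dist <= half).astype(float)
    if flat_caps:
        cov = cov * ((t_raw >= 0.0) & (t_raw <= 1.0))
    return cov


def make_vein_network(
    spec: PhantomSpec,
) -> tuple[np.ndarray, dict]:
    """Random branching network of dark strokes on bright agar.

    Stroke widths come from ``spec.stroke_widths_px`` (cycled across
    branches) or are uniform at ``spec.stroke_width_px``.  Ground truth
    lists per-edge endpoints, widths and lengths plus the rasterized
    projected foreground area; widths must be >= 3 px so the skeleton is
    meaningful.  With ``flat_caps`` each stroke's projected area is exactly
    width × length (the volume-identity oracle); round caps (default) give
    a clean midline skeleton without corner spurs.
    """
    widths = (spec.stroke_widths_px
              if spec.stroke_widths_px is not None
              else (spec.stroke_width_px,))
    if any(w_ < 3 for w_ in widths):
        raise ValidationError("stroke widths must be >= 3 px")
    rng = np.random.default_rng(spec.seed)
    if spec.layout == "separated":
        segments = _separated_segments(rng, spec.shape, spec.n_branches,
                                       max(widths))
    else:
        segments = _random_tree_segments(rng, spec.shape, spec.n_branches)
    coverage = np.zeros(spec.shape)
    edges = []
    for i, (p0, p1) in enumerate(segments):
        w_px = float(widths[i % len(widths)])
        coverage = np.maximum(
            coverage,
            _stroke_coverage(spec.shape, p0, p1, w_px, spec.antialias,
                             flat_caps=spec.flat_caps),
        )
        edges.append({
            "p0": p0, "p1": p1, "width_px": w_px,
            "length_px": float(np.linalg.norm(p1 - p0)),
        })
    img = np.clip(np.rint(AGAR - (AGAR - VEIN) * coverage),
                  0, 255).astype(np.uint8)
    img = _noise(rng, img, spec.noise_sigma)
    truth = {
        "edges": edges,
        "total_length_px": sum(e["length_px"] for e in edges),
        "projected_area_px2": float((coverage >= 0.5).sum()),
        "pixel_pitch": spec.pixel_pitch,
    }
    return img, truth


def make_pulsating_series(
    spec: PhantomSpec,
) -> tuple[FrameSeries, dict]:
    """Vein network whose stroke widths oscillate sinusoidally in time.

    Width follows w(t) = w₀ · (1 + a sin(2πf t + φ)) per frame, sampled at
    ``spec.fs_hz`` for ``spec.n_frames`` frames (900 at 0.25 Hz covers the
    hour-long vein recording).  In chirp mode the instantaneous frequency
    ramps linearly from ``mod_frequency_hz`` to ``chirp_to_hz``.  The
    geometry (a distance field per edge) is computed once, so per-frame
    rendering is a pure threshold of the cached field.
    """
    if spec.mod_frequency_hz >= spec.fs_hz / 2:
        raise ValidationError("modulation frequency must be below Nyquist")
    rng = np.random.default_rng(spec.seed)
    max_w = spec.stroke_width_px * (1.0 + spec.mod_amplitude)
    if spec.layout == "separated":
        segments = _separated_segments(rng, spec.shape, spec.n_branches,
                                       max_w)
    else:
        segments = _random_tree_segments(rng, spec.shape, spec.n_branches)
    if not segments:
        raise ValidationError("phantom produced no strokes; change the seed")
    # cache the distance field of each edge once
    rr, cc = np.meshgrid(np.arange(spec.shape[0]), np.arange(spec.shape[1]),
                         indexing="ij")
    pts = np.stack([rr, cc], axis=-1).astype(float)
    dists = []
    for p0, p1 in segments:
        d = p1 - p0
        L2 = float(d @ d)
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dists.append(np.linalg.norm(pts - proj, axis=-1))
    times = np.arange(spec.n_frames) / spec.fs_hz
    if spec.chirp_to_hz is None:
        phase = 2 * np.pi * spec.mod_frequency_hz * times + spec.mod_phase
    else:
        # linear chirp: φ(t) = 2π (f0 t + (f1−f0) t²/(2T))
        T = times[-1] if times[-1] > 0 else 1.0
        phase = 2 * np.pi * (
            spec.mod_frequency_hz * times
            + (spec.chirp_to_hz - spec.mod_frequency_hz) * times**2 / (2 * T)
        ) + spec.mod_phase
    widths_t = spec.stroke_width_px * (
        1.0 + spec.mod_amplitude * np.sin(phase)
    )
    frames = []
    for w_t in widths_t:
        half = w_t / 2.0
        coverage = np.zeros(spec.shape)
        for dist in dists:
            if spec.antialias:
                cov = np.clip(half + 0.5 - dist, 0.0, 1.0)
            else:
                cov = (dist <= half).astype(float)
            coverage = np.maximum(coverage, cov)
        img = np.clip(np.rint(AGAR - (AGAR - VEIN) * coverage),
                      0, 255).astype(np.uint8)
        frames.append(_noise(rng, img, spec.noise_sigma))
    series = FrameSeries(
        frames, times, pixel_pitch=spec.pixel_pitch,
        source_paths=[f"phantom:pulse:{spec.seed}:{i}"
                      for i in range(spec.n_frames)],
    )
    truth = {
        "frequency_hz": spec.mod_frequency_hz,
        "chirp_to_hz": spec.chirp_to_hz,
        "amplitude": spec.mod_amplitude,
        "phase": spec.mod_phase,
        "width0_px": spec.stroke_width_px,
        "widths_px": widths_t,
        "segments": segments,
    }
    return series, truth


def make_fractal_pattern(
    kind: str, depth: int = 7, size: int | None = None
) -> tuple[np.ndarray, float]:
    """Exact fractal raster and its analytic box dimension.

    ``line`` (D = 1), ``filled_square`` (D = 2) or ``sierpinski`` at the
    given depth (D = log 3 / log 2 ≈ 1.585, rasterized exactly on a
    2^depth canvas via the binary-AND construction).
    """
    if kind == "sierpinski":
        n = 2**depth
        if size is not None and size != n:
            raise ValidationError("sierpinski size is fixed at 2**depth")
        x = np.arange(n)
        mask = (x[:, None] & x[None, :]) == 0
        return mask, float(np.log(3) / np.log(2))
    n = size if size is not None else 2**depth
    if kind == "filled_square":
        return np.ones((n, n), bool), 2.0
    if kind == "line":
        mask = np.zeros((n, n), bool)
        mask[n // 2, :] = True
        return mask, 1.0
    raise ValidationError(f"unknown fractal kind: {kind!r}")
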