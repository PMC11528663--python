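"""Network volume estimation from 2-D projections with geometric error bounds.

Only a top-down projection of the network is available, so the volume model
treats the network as a collection of cylindrical sections.  The measured
vein diameters are binned into N intervals (default 50) of width

    stepsize = (max diameter − min diameter) / N

and each interval k, with centre diameter 2r_k and occupancy fraction p_k,
is assigned the share p_k of the total projected biomass area A (mm² at
24 h).  A cylinder of diameter 2r_k projects area 2r_k × length, so the
interval's total vein length is

    l_k = A · p_k / (2 r_k)

and the network volume is the sum of cylinder volumes

    est. vol = Σ_k π r_k² l_k        (mm³).

Dividing by A gives the *normalized volume* (mm) — an effective mean
thickness of the network, comparable across organisms of different size.

Because a vein cross-section need not be circular, two closed-form relative
errors bound the bias of the circular assumption, both expressed through
the area ratio (A_C − A_X)/A_X of the circular cross-section to the
alternative of equal horizontal diameter 2r:

* circular-segment cross-section missing a cap of central angle α:
      ε_S(α) = (α − sin α) / (2π − (α − sin α)),      0 ≤ α < 2π
* elliptical cross-section flattened by x (semi-minor axis r − x/2):
      ε_E(x) = x / (2r − x),                          0 ≤ x < 2r

Both vanish for the circular case and increase monotonically with the
deformation, so evaluating them at worst-case α and x brackets the true
volume from below: true ∈ [est/(1+ε_max), est].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import ValidationError

__all__ = [
    "DiameterDistribution",
    "VolumeEstimate",
    "diameter_distribution",
    "interval_length",
    "estimate_volume",
    "normalized_volume",
    "segment_error",
    "ellipse_error",
    "error_curves",
]


@dataclass
class DiameterDistribution:
    """Binned vein-diameter proportions.

    ``edges`` (µm) bound ``n_intervals`` equal-width intervals covering
    [min, max] of the measured diameters; ``centers_um`` are the interval
    centres (the 2r of the volume model) and ``proportions`` the fraction
    of measurements per interval (summing to 1).
    """

    n_intervals: int
    edges: np.ndarray  # µm, length n_intervals + 1
    centers_um: np.ndarray
    proportions: np.ndarray
    stepsize_um: float
    delta_um: float

    def __post_init__(self) -> None:
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("proportions must sum to 1")
        if np.any(np.diff(self.centers_um) <= 0) and self.n_intervals > 1:
            raise ValidationError("interval centres must strictly increase")


@dataclass
class VolumeEstimate:
    """Estimated network volume with per-interval decomposition.

    ``per_interval`` rows are (r_mm, length_mm, volume_mm3); ``total_mm3``
    is their volume sum and ``normalized_mm`` the total divided by the
    projected area.  ``error_range`` holds (ε_S, ε_E) at the worst-case
    geometry parameters and ``volume_interval_mm3`` the implied bracket
    [total/(1+ε_max), total].
    """

    total_mm3: float
    per_interval: np.ndarray  # (n, 3): r_mm, l_mm, vol_mm3
    area_mm2: float
    normalized_mm: float
    error_range: tuple[float, float] | None = None
    volume_interval_mm3: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.total_mm3 < 0 or self.normalized_mm < 0:
            raise ValidationError("volume quantities must be non-negative")
        if abs(self.per_interval[:, 2].sum() - self.total_mm3) > \
                1e-9 * max(self.total_mm3, 1.0):
            raise ValidationError("interval volumes must sum to the total")


def diameter_distribution(
    widths_um: np.ndarray, n_intervals: int = 50
) -> DiameterDistribution:
    """Bin measured vein diameters into equal-width intervals.

    Intervals are half-open with the last closed (a measurement equal to
    the maximum lands in the final interval).  If every width is identical
    the distribution degenerates to a single interval at that value.
    """
    w = np.asarray(widths_um, float)
    w = w[w > 0]
    if w.size == 0:
        raise ValidationError("need at least one positive width")
    wmin, wmax = float(w.min()), float(w.max())
    if wmax == wmin:
        # degenerate: all mass in one interval at the common value
        return DiameterDistribution(
            n_intervals=1,
            edges=np.array([wmin, wmax]),
            centers_um=np.array([wmin]),
            proportions=np.array([1.0]),
            stepsize_um=0.0,
            delta_um=0.0,
        )
    counts, edges = np.histogram(w, bins=n_intervals, range=(wmin, wmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DiameterDistribution(
        n_intervals=n_intervals,
        edges=edges,
        centers_um=centers,
        proportions=counts / counts.sum(),
        stepsize_um=(wmax - wmin) / n_intervals,
        delta_um=wmax - wmin,
    )


def interval_length(area_mm2: float, p: float, two_r_um: float) -> float:
    """Vein length (mm) carried by one diameter interval: l = A·p / (2r)."""
    if two_r_um <= 0:
        raise ValidationError("interval diameter must be positive")
    if p < 0:
        raise ValidationError("proportion must be non-negative")
    two_r_mm = two_r_um / 1000.0
    return area_mm2 * p / two_r_mm


def estimate_volume(
    dist: DiameterDistribution,
    area_mm2: float,
    alpha_max: float | None = None,
    x_max_frac: float | None = None,
) -> VolumeEstimate:
    """Total network volume under the cylindrical-section model (mm³).

    Optionally evaluates the geometric error bounds at a worst-case
    circular-segment angle ``alpha_max`` (radians) and ellipse flattening
    ``x_max_frac`` (fraction of 2r), attaching the implied volume bracket.
    """
    if area_mm2 < 0:
        raise ValidationError("area must be non-negative")
    rows = np.zeros((dist.n_intervals, 3))
    for k in range(dist.n_intervals):
        two_r_um = float(dist.centers_um[k])
        p = float(dist.proportions[k])
        r_mm = two_r_um / 2000.0
        l_mm = interval_length(area_mm2, p, two_r_um) if p > 0 else 0.0
        rows[k] = (r_mm, l_mm, np.pi * r_mm**2 * l_mm)
    total = float(rows[:, 2].sum())
    norm = total / area_mm2 if area_mm2 > 0 else 0.0
    err = interval = None
    if alpha_max is not None or x_max_frac is not None:
        e_s = segment_error(alpha_max) if alpha_max is not None else 0.0
        e_e = 0.0
        if x_max_frac is not None:
            # ε_E depends only on x/2r; evaluate with a unit diameter
            e_e = ellipse_error(x_max_frac, 0.5)
        err = (e_s, e_e)
        e_max = max(e_s, e_e)
        interval = (total / (1.0 + e_max), total)
    return VolumeEstimate(
        total_mm3=total,
        per_interval=rows,
        area_mm2=float(area_mm2),
        normalized_mm=norm,
        error_range=err,
        volume_interval_mm3=interval,
    )


def normalized_volume(vol: VolumeEstimate, area_mm2_at_24h: float) -> float:
    """Volume per unit projected biomass area at 24 h (mm)."""
    if area_mm2_at_24h <= 0:
        raise ValidationError("normalization area must be positive")
    return vol.total_mm3 / area_mm2_at_24h


def segment_error(alpha: float | np.ndarray) -> float | np.ndarray:
    """Relative volume error for a circular-segment cross-section.

    ε_S(α) = (α − sin α) / (2π − (α − sin α)) for the central angle α of
    the missing cap, 0 ≤ α < 2π.  ε_S(0) = 0 (full circle), ε_S(π) = 1,
    and ε_S diverges as α → 2π.
    """
    a = np.asarray(alpha, float)
    if np.any(a < 0) or np.any(a >= 2 * np.pi):
        raise ValidationError("alpha must lie in [0, 2π)")
    cap = a - np.sin(a)
    with np.errstate(divide="ignore"):  # diverges as α → 2π
        out = cap / (2 * np.pi - cap)
    return float(out) if np.isscalar(alpha) else out


def ellipse_error(x: float | np.ndarray, r: float) -> float | np.ndarray:
    """Relative volume error for an elliptical cross-section.

    ε_E(x) = x / (2r − x) where x is the flattening of the vertical
    diameter (semi-minor axis r − x/2), 0 ≤ x < 2r.  ε_E(0) = 0 (circle)
    and ε_E(r) = 1.
    """
    if r <= 0:
        raise ValidationError("radius must be positive")
    xv = np.asarray(x, float)
    if np.any(xv < 0) or np.any(xv >= 2 * r):
        raise ValidationError("x must lie in [0, 2r)")
    out = xv / (2 * r - xv)
    return float(out) if np.isscalar(x) else out


def error_curves(
    alpha_grid: np.ndarray, x_grid: np.ndarray, r: float
) -> dict[str, np.ndarray]:
    """Tabulated ε_S and ε_E over parameter grids (for plotting)."""
    alpha_grid = np.asarray(alpha_grid, float)
    x_grid = np.asarray(x_grid, float)
    return {
        "alpha": alpha_grid,
        "eps_segment": (segment_error(alpha_grid)
                        if alpha_grid.size else np.empty(0)),
        "x": x_grid,
        "eps_ellipse": (ellipse_error(x_grid, r)
                        if x_grid.size else np.empty(0)),
    }
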