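"""Run configuration and pipeline orchestration.

A :class:`RunConfig` collects every stage parameter plus input/output paths
and round-trips losslessly through YAML; unknown keys are rejected so typos
fail loudly.  :func:`run_pipeline` chains the stages — growth segmentation
→ fractal complexity → vein morphometry → contraction spectra → volume —
writing one CSV/JSON artifact per stage and a manifest recording the
package version, seed and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import fractal as fractal_mod
from . import growth as growth_mod
from . import spectral as spectral_mod
from . import veins as veins_mod
from . import volume as volume_mod
from .imaging_io import (
    FrameSeries,
    ScaleCalibration,
    ValidationError,
    DetectionError,
    apply_roi,
    denoise_frame,
    detect_dish_roi,
    load_frame_series,
)

logger = logging.getLogger("physarum_morph")

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


def _strict_from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}"
        )
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _strict_from_dict(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class DenoiseConfig:
    strength: float = 8.0
    template_window: int = 5
    search_window: int = 21


@dataclass
class RoiConfig:
    enabled: bool = True
    min_radius: int = 1500
    max_radius: int = 1750
    min_dist: int = 563


@dataclass
class ScaleConfig:
    length_px: float = 1000.0
    length_mm: float = 10.0


@dataclass
class GrowthConfig:
    window: int = 71
    offset: float = 4.0
    interval_s: float = 60.0
    horizon_h: float = 24.0


@dataclass
class FractalConfig:
    every_minutes: float = 10.0


@dataclass
class VeinConfig:
    window: int = veins_mod.VEIN_WINDOW_DEFAULT
    offset: float = veins_mod.VEIN_OFFSET_DEFAULT
    interval_s: float = 4.0
    hough_threshold: int = 25
    min_line_length: int = 10
    contrast_min: float = 10.0
    max_mean_width_um: float = 1000.0


@dataclass
class SpectralConfig:
    fs_hz: float = 0.25
    segment_length: int = 256
    overlap: float = 0.9


@dataclass
class VolumeConfig:
    n_intervals: int = 50
    alpha_max: float | None = None
    x_max_frac: float | None = None


@dataclass
class RunConfig:
    """Full pipeline configuration (serializes to/from YAML)."""

    growth_frames: str | None = None
    vein_frames: str | None = None
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    fractal: FractalConfig = field(default_factory=FractalConfig)
    veins: VeinConfig = field(default_factory=VeinConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    volume: VolumeConfig = field(default_factory=VolumeConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        sub = {
            "denoise": DenoiseConfig, "roi": RoiConfig, "scale": ScaleConfig,
            "growth": GrowthConfig, "fractal": FractalConfig,
            "veins": VeinConfig, "spectral": SpectralConfig,
            "volume": VolumeConfig,
        }
        kwargs = {}
        for k, v in data.items():
            kwargs[k] = _strict_from_dict(sub[k], v) if k in sub else v
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _prepare_series(series: FrameSeries, cfg: RunConfig) -> FrameSeries:
    """Denoise every frame and blank the region outside the dish."""
    roi = None
    if cfg.roi.enabled:
        try:
            roi = detect_dish_roi(
                series.frames[0], cfg.roi.min_radius, cfg.roi.max_radius,
                cfg.roi.min_dist,
            )
        except DetectionError as exc:
            logger.warning("ROI detection failed (%s); using full frame", exc)
    frames = []
    for f in series.frames:
        g = denoise_frame(f, cfg.denoise.strength,
                          cfg.denoise.template_window,
                          cfg.denoise.search_window)
        frames.append(apply_roi(g, roi) if roi is not None else g)
    out = FrameSeries(frames, series.timestamps,
                      pixel_pitch=series.pixel_pitch,
                      source_paths=series.source_paths)
    out.roi = roi  # noqa: attribute used downstream for segmentation
    return out


def run_growth_stage(series: FrameSeries, cfg: RunConfig,
                     cal: ScaleCalibration, out: Path) -> dict:
    params = growth_mod.SegmentationParams(cfg.growth.window,
                                           cfg.growth.offset)
    roi = getattr(series, "roi", None)
    roi_mask = roi.mask if roi is not None else None
    masks = growth_mod.segment_series(series, params, roi_mask)
    areas = growth_mod.area_series(masks, cal, series.timestamps)
    expl = growth_mod.exploration_series(masks, cal, series.timestamps)
    pd.DataFrame({
        "t_hours": areas.times_h,
        "area_mm2": areas.area_mm2,
        "area_norm_mm2": areas.area_norm_mm2,
        "explored_mm2": expl.explored_mm2,
    }).to_csv(out / "growth.csv", index=False)
    horizon = min(cfg.growth.horizon_h, areas.times_h[-1])
    summary = {
        "growth_rate": growth_mod.growth_rate(areas, horizon),
        "exploration_rate_mm2_per_h":
            growth_mod.exploration_rate(expl, horizon),
        "area_t0_mm2": areas.a_t0,
        "area_t_end_mm2": float(areas.area_mm2[-1]),
    }
    (out / "growth_summary.json").write_text(json.dumps(summary, indent=2))
    fr = fractal_mod.fractal_series(masks, series.timestamps,
                                    cfg.fractal.every_minutes)
    pd.DataFrame({
        "t_hours": fr.times_h, "dimension": fr.dimension,
        "fit_r2": fr.fit_r2,
    }).to_csv(out / "fractal.csv", index=False)
    summary["final_fractal_dimension"] = float(fr.dimension[-1])
    summary["area_t24_mm2"] = areas.area_at(horizon)
    return summary


def run_vein_stage(series: FrameSeries, cfg: RunConfig,
                   cal: ScaleCalibration, out: Path) -> dict:
    first = np.asarray(series.frames[0], float)
    params = growth_mod.SegmentationParams(cfg.veins.window, cfg.veins.offset)
    mask = growth_mod.segment_network(first, params)
    skel = veins_mod.skeletonize(mask)
    sections = veins_mod.detect_sections(
        skel, threshold=cfg.veins.hough_threshold,
        min_line_length=cfg.veins.min_line_length, seed=cfg.seed,
    )
    sections, first_widths = veins_mod.qc_cascade(
        sections, first, cal.pixel_pitch,
        max_mean_width_um=cfg.veins.max_mean_width_um,
        contrast_min=cfg.veins.contrast_min,
    )
    rows = []
    for sec in sections:
        for k, (p, n) in enumerate(zip(sec.measurement_positions,
                                       sec.normals)):
            rows.append({
                "section_id": sec.section_id, "pos_index": k,
                "y_px": p[0], "x_px": p[1], "ny": n[0], "nx": n[1],
                "status": ("active" if sec.status == "active"
                           and sec.position_active[k] else "rejected"),
                "reject_reason": sec.reject_reason,
            })
    pd.DataFrame(rows).to_csv(out / "sections.csv", index=False)
    traces = veins_mod.track_sections(series, sections, cal)
    pd.concat([
        pd.DataFrame({
            "section_id": tr.section_id, "pos_index": tr.position_index,
            "t_seconds": tr.times_s, "width_um": tr.width_um,
        }) for tr in traces
    ], ignore_index=True).to_csv(out / "widths.csv", index=False) \
        if traces else pd.DataFrame(
            columns=["section_id", "pos_index", "t_seconds", "width_um"]
        ).to_csv(out / "widths.csv", index=False)
    return {
        "n_sections_active":
            sum(s.status == "active" for s in sections),
        "n_sections_total": len(sections),
        "n_traces": len(traces),
    }


def run_contraction_stage(cfg: RunConfig, out: Path) -> dict:
    widths = pd.read_csv(out / "widths.csv")
    if widths.empty:
        logger.warning("no width traces; contraction stage skipped")
        return {}
    sc = cfg.spectral
    rows, estimates, ids = [], [], []
    for sid, grp in widths.groupby("section_id"):
        # average positions of a section into one trace
        trace = (grp.pivot_table(index="t_seconds", values="width_um",
                                 aggfunc="mean").squeeze("columns")
                 .to_numpy())
        if trace.size < sc.segment_length:
            continue
        est = spectral_mod.contraction_frequency(
            trace, sc.fs_hz, sc.segment_length, sc.overlap
        )
        estimates.append(est)
        ids.append(int(sid))
        for k, f in enumerate(est.slice_freqs):
            rows.append({"section_id": sid, "slice_index": k,
                         "slice_freq_hz": f,
                         "est_frequency_hz": est.est_frequency_hz,
                         "low_confidence": est.low_confidence})
    if not estimates:
        return {}
    org = spectral_mod.organism_average(estimates, ids)
    df = pd.DataFrame(rows)
    df["outlier_flag"] = df["section_id"].isin(org.excluded_ids)
    df.to_csv(out / "frequency.csv", index=False)
    summary = {
        "organism_mean_hz": org.mean_hz, "organism_sd_hz": org.sd_hz,
        "n_sections": org.n_sections, "excluded_ids": org.excluded_ids,
    }
    (out / "frequency_summary.json").write_text(
        json.dumps(summary, indent=2))
    return summary


def run_volume_stage(cfg: RunConfig, out: Path, area_mm2: float) -> dict:
    widths = pd.read_csv(out / "widths.csv")
    if widths.empty:
        return {}
    # per-position time-mean widths, pooled over sections
    pooled = widths.groupby(["section_id", "pos_index"])["width_um"] \
        .mean().to_numpy()
    dist = volume_mod.diameter_distribution(pooled, cfg.volume.n_intervals)
    est = volume_mod.estimate_volume(dist, area_mm2,
                                     cfg.volume.alpha_max,
                                     cfg.volume.x_max_frac)
    pd.DataFrame(est.per_interval,
                 columns=["r_mm", "length_mm", "volume_mm3"]) \
        .to_csv(out / "volume_intervals.csv", index=False)
    summary = {
        "total_mm3": est.total_mm3,
        "normalized_mm": est.normalized_mm,
        "area_mm2": est.area_mm2,
        "error_range": est.error_range,
        "volume_interval_mm3": est.volume_interval_mm3,
    }
    (out / "volume.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(
    cfg: RunConfig,
    growth_series: FrameSeries | None = None,
    vein_series: FrameSeries | None = None,
) -> dict:
    """Execute every stage whose inputs are available.

    Frame series may be passed directly (phantoms, tests) or read from the
    directories named in the config.  Returns the merged stage summaries;
    all artifacts land in ``cfg.out_dir`` together with a run manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    cal = ScaleCalibration(
        pixel_pitch=1000.0 * cfg.scale.length_mm / cfg.scale.length_px,
        source="config",
    )
    if growth_series is None and cfg.growth_frames:
        paths = sorted(Path(cfg.growth_frames).glob("*.png")) + \
            sorted(Path(cfg.growth_frames).glob("*.tif*"))
        if not paths:
            raise FileNotFoundError(
                f"no frames found in {cfg.growth_frames}")
        growth_series = load_frame_series(paths, cfg.growth.interval_s,
                                          cal.pixel_pitch)
    if vein_series is None and cfg.vein_frames:
        paths = sorted(Path(cfg.vein_frames).glob("*.png")) + \
            sorted(Path(cfg.vein_frames).glob("*.tif*"))
        if not paths:
            raise FileNotFoundError(f"no frames found in {cfg.vein_frames}")
        vein_series = load_frame_series(paths, cfg.veins.interval_s,
                                        cal.pixel_pitch)

    results: dict = {}
    if growth_series is not None:
        prepped = _prepare_series(growth_series, cfg)
        results["growth"] = run_growth_stage(prepped, cfg, cal, out)
    if vein_series is not None:
        prepped = _prepare_series(vein_series, cfg)
        results["veins"] = run_vein_stage(prepped, cfg, cal, out)
        results["contraction"] = run_contraction_stage(cfg, out)
        area = results.get("growth", {}).get("area_t24_mm2")
        if area:
            results["volume"] = run_volume_stage(cfg, out, area)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": sorted(results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
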