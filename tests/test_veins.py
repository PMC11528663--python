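"""Skeletonization, section detection, width rays and the QC cascade."""

import numpy as np
import pytest

from physarum_morph import growth, phantom, veins
from physarum_morph.imaging_io import ScaleCalibration
from physarum_morph.veins import (
    VeinSection,
    detect_sections,
    measure_width,
    qc_cascade,
    qc_colour_gradient,
    qc_initial_size,
    qc_median_comparison,
    qc_overlap,
    qc_positional_consistency,
    skeletonize,
    track_sections,
)


def _count_neighbors(skel):
    from scipy import ndimage
    kernel = np.ones((3, 3)); kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _make_section(sid=0, n=4, y=10.0, x0=5.0, spacing=5.0, status="active"):
    pos = np.array([[y, x0 + i * spacing] for i in range(n)])
    normals = np.tile([1.0, 0.0], (n, 1))
    return VeinSection(
        section_id=sid,
        detection_line=((y, x0), (y, x0 + (n - 1) * spacing)),
        measurement_positions=pos,
        normals=normals,
        status=status,
    )


class TestSkeletonize:
    def test_wide_bar_thins_to_single_line(self):
        mask = np.zeros((40, 80), bool)
        mask[18:23, 10:70] = True  # 5 px wide bar
        skel = skeletonize(mask)
        cols = skel[:, 20:60]
        assert np.all(cols.sum(axis=0) == 1)

    def test_filled_disc_collapses(self):
        mask = np.zeros((60, 60), bool)
        yy, xx = np.ogrid[:60, :60]
        mask[(yy - 30)**2 + (xx - 30)**2 <= 15**2] = True
        skel = skeletonize(mask)
        assert skel.sum() < 0.05 * mask.sum()

    def test_y_junction_topology(self):
        # three 9-px strokes meeting at a point: 3 endpoints, >=1 branch
        img = np.zeros((160, 160), float) + 220
        c = np.array([80.0, 80.0])
        for ang in (90, 210, 330):
            a = np.radians(ang)
            tip = c + 60 * np.array([np.sin(a), np.cos(a)])
            cov = phantom._stroke_coverage((160, 160), c, tip, 9.0, True)
            img = np.minimum(img, 220 - 160 * cov)
        mask = growth.segment_network(img, growth.SegmentationParams(79, 2))
        skel = skeletonize(mask)
        nb = _count_neighbors(skel)
        endpoints = int(((nb == 1) & skel).sum())
        branch_pts = int(((nb >= 3) & skel).sum())
        assert endpoints == 3
        assert branch_pts >= 1

    def test_empty_mask_gives_empty_skeleton(self):
        assert skeletonize(np.zeros((10, 10), bool)).sum() == 0

    def test_skeleton_single_pixel_wide_for_random_strokes(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            w = rng.uniform(3, 15)
            p0 = rng.uniform(20, 40, 2)
            p1 = rng.uniform(80, 120, 2)
            cov = phantom._stroke_coverage((140, 140), p0, p1, w, False)
            skel = skeletonize(cov >= 0.5)
            nb = _count_neighbors(skel)
            # no skeleton pixel may sit in a 2x2 solid block
            s = skel.astype(int)
            blocks = s[:-1, :-1] + s[1:, :-1] + s[:-1, 1:] + s[1:, 1:]
            assert blocks.max() <= 3


class TestDetectSections:
    def test_straight_skeleton_orientation(self):
        skel = np.zeros((120, 120), bool)
        rr = np.arange(100)
        skel[10 + rr // 2, 10 + rr] = True  # ~26.6° line
        secs = detect_sections(skel, threshold=25, min_line_length=10)
        assert len(secs) >= 1
        (p0, p1) = secs[0].detection_line
        ang = np.degrees(np.arctan2(p1[0] - p0[0], p1[1] - p0[1])) % 180.0
        assert abs(ang - 26.57) < 2.0

    def test_empty_skeleton_gives_empty_list(self):
        assert detect_sections(np.zeros((50, 50), bool)) == []

    def test_min_line_length_gates_detection(self):
        def skel_of(length):
            s = np.zeros((40, 40), bool)
            s[20, 5: 5 + length] = True
            return s
        long = detect_sections(skel_of(12), threshold=5, min_line_length=10)
        short = detect_sections(skel_of(8), threshold=5, min_line_length=10)
        assert len(long) >= 1
        assert len(short) == 0

    def test_sections_carry_at_least_four_positions(self, vein_phantom):
        frame, _, _ = vein_phantom
        mask = growth.segment_network(np.asarray(frame, float),
                                      growth.SegmentationParams(79, 2))
        secs = detect_sections(skeletonize(mask))
        assert len(secs) >= 1
        for s in secs:
            assert len(s.measurement_positions) >= 4
            assert np.allclose(np.linalg.norm(s.normals, axis=1), 1.0)


class TestMeasureWidth:
    def test_phantom_stroke_width_recovered(self):
        img = np.full((100, 200), 220.0)
        cov = phantom._stroke_coverage((100, 200), np.array([50.0, 10.0]),
                                       np.array([50.0, 190.0]), 20.0, True)
        img -= 160 * cov
        w = measure_width(img, np.array([50.0, 100.0]),
                          np.array([1.0, 0.0]), stop_intensity=140.0,
                          pixel_pitch=10.0)
        assert w == pytest.approx(200.0, abs=20.0)

    def test_background_position_is_zero(self):
        img = np.full((50, 50), 220.0)
        w = measure_width(img, np.array([25.0, 25.0]),
                          np.array([1.0, 0.0]), 140.0, 10.0)
        assert w == 0.0

    def test_uniform_vein_consistent_across_positions(self, vein_phantom):
        frame, truth, spec = vein_phantom
        mask = growth.segment_network(np.asarray(frame, float),
                                      growth.SegmentationParams(79, 2))
        secs = detect_sections(skeletonize(mask))
        secs, widths = qc_cascade(secs, np.asarray(frame, float), 10.0)
        checked = 0
        for s, w in zip(secs, widths):
            if s.status != "active":
                continue
            act = w[s.position_active]
            assert act.max() - act.min() <= 2 * 10.0  # 2 px at 10 µm/px
            checked += 1
        assert checked >= 1


class TestQcFilters:
    def test_size_filter_boundaries(self):
        secs = [_make_section(i) for i in range(3)]
        widths = [np.full(4, 1200.0), np.full(4, 300.0), np.full(4, 1000.0)]
        out = qc_initial_size(secs, widths)
        assert out[0].status == "rejected" and out[0].reject_reason == "size"
        assert out[1].status == "active"
        assert out[2].status == "active"  # exactly 1 mm: strict >

    def test_consistency_drops_outlier_and_rejects_short(self):
        sec = _make_section(0, n=4)
        out = qc_positional_consistency([sec], [np.array([10., 10., 10., 40.])])
        assert out[0].status == "rejected"
        assert out[0].reject_reason == "consistency"

    def test_consistency_keeps_four_of_five(self):
        sec = _make_section(0, n=5)
        out = qc_positional_consistency(
            [sec], [np.array([10., 10., 10., 10., 40.])])
        assert out[0].status == "active"
        assert out[0].n_active == 4

    def test_consistency_mild_spread_stays_active(self):
        sec = _make_section(0, n=5)
        out = qc_positional_consistency(
            [sec], [np.array([10., 10., 11., 10., 10.])])
        assert out[0].status == "active"
        assert out[0].n_active >= 4

    def test_median_comparison_rejects_double(self):
        secs = [_make_section(i) for i in range(3)]
        widths = [np.full(4, 10.0), np.full(4, 10.0), np.full(4, 25.0)]
        out = qc_median_comparison(secs, widths)
        statuses = [s.status for s in out]
        assert statuses == ["active", "active", "rejected"]
        assert out[2].reject_reason == "median"

    def test_median_comparison_tolerates_moderate_spread(self):
        secs = [_make_section(i) for i in range(2)]
        widths = [np.full(4, 10.0), np.full(4, 20.0)]
        out = qc_median_comparison(secs, widths)
        assert all(s.status == "active" for s in out)  # 20 <= 2 × 15

    def test_median_equal_sections_all_kept(self):
        secs = [_make_section(i) for i in range(4)]
        widths = [np.full(4, 12.0)] * 4
        out = qc_median_comparison(secs, widths)
        assert all(s.status == "active" for s in out)

    def test_contrast_filter(self):
        img = np.full((60, 60), 200.0)
        img[8:13, :] = 60.0  # strong vein at the first section
        sec_good = _make_section(0, y=10.0, x0=10.0)
        sec_bad = _make_section(1, y=40.0, x0=10.0)  # uniform region
        out = qc_colour_gradient([sec_good, sec_bad], img)
        assert out[0].status == "active"
        assert out[1].status == "rejected"
        assert out[1].reject_reason == "contrast"

    def test_overlap_keeps_one_of_duplicates(self):
        a = _make_section(0)
        b = _make_section(1)  # identical geometry
        out = qc_overlap([a, b])
        statuses = sorted(s.status for s in out)
        assert statuses == ["active", "rejected"]
        kept = [s for s in out if s.status == "active"][0]
        assert kept.section_id == 0  # tie → lower id survives

    def test_overlap_disjoint_both_survive(self):
        a = _make_section(0, y=10.0)
        b = _make_section(1, y=40.0)
        out = qc_overlap([a, b])
        assert all(s.status == "active" for s in out)

    def test_overlap_crossing_x_keeps_exactly_one(self):
        pos_a = np.array([[10.0 + i * 5, 10.0 + i * 5] for i in range(4)])
        d = np.array([1.0, 1.0]) / np.sqrt(2)
        a = VeinSection(0, ((10.0, 10.0), (25.0, 25.0)), pos_a,
                        np.tile([-d[1], d[0]], (4, 1)))
        pos_b = np.array([[25.0 - i * 5, 10.0 + i * 5] for i in range(4)])
        e = np.array([-1.0, 1.0]) / np.sqrt(2)
        b = VeinSection(1, ((25.0, 10.0), (10.0, 25.0)), pos_b,
                        np.tile([-e[1], e[0]], (4, 1)))
        out = qc_overlap([a, b])
        assert sorted(s.status for s in out) == ["active", "rejected"]


class TestCascade:
    def test_cascade_idempotent(self, vein_phantom):
        frame, _, _ = vein_phantom
        frame_f = np.asarray(frame, float)
        mask = growth.segment_network(frame_f,
                                      growth.SegmentationParams(79, 2))
        secs = detect_sections(skeletonize(mask))
        once, widths = qc_cascade(secs, frame_f, 10.0)
        twice, _ = qc_cascade(once, frame_f, 10.0)
        for s1, s2 in zip(once, twice):
            assert s1.status == s2.status
            assert s1.reject_reason == s2.reject_reason
            assert np.array_equal(s1.position_active, s2.position_active)


class TestTrackSections:
    def test_static_phantom_constant_traces(self, vein_phantom, cal10):
        from physarum_morph.imaging_io import FrameSeries
        frame, _, _ = vein_phantom
        series = FrameSeries([frame] * 5, np.arange(5) * 4.0,
                             pixel_pitch=10.0)
        frame_f = np.asarray(frame, float)
        mask = growth.segment_network(frame_f,
                                      growth.SegmentationParams(79, 2))
        secs = detect_sections(skeletonize(mask))
        secs, _ = qc_cascade(secs, frame_f, 10.0)
        traces = track_sections(series, secs, cal10)
        assert len(traces) > 0
        for tr in traces:
            assert tr.width_um.max() - tr.width_um.min() <= 10.0  # ±1 px

    def test_pulsating_phantom_trace_correlates(self, pulsating_phantom,
                                                cal10):
        series, truth = pulsating_phantom
        frame_f = np.asarray(series.frames[0], float)
        mask = growth.segment_network(frame_f,
                                      growth.SegmentationParams(79, 2))
        secs = detect_sections(skeletonize(mask), spacing_px=30.0)
        secs, _ = qc_cascade(secs, frame_f, 10.0)
        traces = track_sections(series, secs, cal10)
        assert len(traces) >= 1
        assert len(traces[0].times_s) == 900
        gen = truth["widths_px"]
        r = np.corrcoef(traces[0].width_um, gen)[0, 1]
        assert r > 0.9
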