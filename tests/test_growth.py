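"""Segmentation, area/exploration series and dose–response quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physarum_morph import growth
from physarum_morph.growth import (
    AreaSeries,
    ExplorationSeries,
    SegmentationParams,
    area_series,
    exploration_rate,
    exploration_series,
    fit_dose_response,
    growth_inhibition,
    growth_rate,
    segment_network,
)
from physarum_morph.imaging_io import ScaleCalibration, ValidationError
from physarum_morph import phantom


class TestSegmentation:
    def test_uniform_frame_gives_empty_foreground(self):
        frame = np.full((128, 128), 180.0)
        assert segment_network(frame).sum() == 0

    def test_dark_disc_on_bright_agar_recovered(self):
        spec = phantom.PhantomSpec(kind="growing_disk", shape=(200, 200),
                                   disk_radius0=18, n_frames=1,
                                   noise_sigma=0, seed=0, antialias=False)
        series, truth = phantom.make_growing_disk_series(spec)
        fg = segment_network(np.asarray(series.frames[0], float))
        drawn = np.pi * 18**2
        assert fg.sum() == pytest.approx(drawn, rel=0.03)

    def test_inverse_polarity_bright_organism_not_detected(self):
        # bright disc on dark field: the inverse threshold must stay silent
        spec = phantom.PhantomSpec(kind="growing_disk", shape=(200, 200),
                                   disk_radius0=18, n_frames=1,
                                   noise_sigma=0, seed=0, antialias=False)
        series, _ = phantom.make_growing_disk_series(spec)
        inverted = 255 - np.asarray(series.frames[0], float)
        fg = segment_network(inverted)
        yy, xx = np.ogrid[:200, :200]
        disc = (yy - 100) ** 2 + (xx - 100) ** 2 <= 17**2
        assert fg[disc].sum() < 0.05 * disc.sum()

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            SegmentationParams(window=70)


class TestAreaSeries:
    def test_unit_arithmetic(self, cal10):
        mask = np.zeros((200, 200), bool)
        mask.flat[:10_000] = True  # 10 000 px at 10 µm/px = 1 mm²
        s = area_series([mask], cal10, np.array([0.0]))
        assert s.area_mm2[0] == pytest.approx(1.0)

    def test_constant_masks_have_zero_normalised_area(self, cal10):
        mask = np.ones((50, 50), bool)
        s = area_series([mask] * 4, cal10, np.arange(4) * 60.0)
        assert np.allclose(s.area_norm_mm2, 0.0)

    def test_growing_disk_matches_analytic_area(self, cal10, doubling_disk):
        series, truth = doubling_disk
        masks = growth.segment_series(series)
        s = area_series(masks, cal10, series.timestamps)
        assert np.allclose(s.area_mm2, truth["area_mm2"], rtol=0.03)

    def test_empty_series_rejected(self, cal10):
        with pytest.raises(ValidationError):
            area_series([], cal10, np.array([]))


class TestGrowthRate:
    def test_no_growth_is_zero(self):
        s = AreaSeries(times_h=np.array([0.0, 24.0]),
                       area_mm2=np.array([5.0, 5.0]))
        assert growth_rate(s) == 0.0

    def test_doubling_is_one(self):
        s = AreaSeries(times_h=np.array([0.0, 24.0]),
                       area_mm2=np.array([5.0, 10.0]))
        assert growth_rate(s) == pytest.approx(1.0)

    def test_doubling_disk_phantom(self, cal10, doubling_disk):
        series, _ = doubling_disk
        masks = growth.segment_series(series)
        s = area_series(masks, cal10, series.timestamps)
        assert growth_rate(s) == pytest.approx(1.0, abs=0.03)

    def test_zero_baseline_rejected(self):
        s = AreaSeries(times_h=np.array([0.0, 24.0]),
                       area_mm2=np.array([0.0, 10.0]))
        with pytest.raises(ValidationError, match="A_t0"):
            growth_rate(s)

    def test_short_series_rejected(self):
        s = AreaSeries(times_h=np.array([0.0, 12.0]),
                       area_mm2=np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            growth_rate(s)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = np.array([2.0, 3.0, 5.0])
        t = np.array([0.0, 12.0, 24.0])
        r1 = growth_rate(AreaSeries(times_h=t, area_mm2=base))
        r2 = growth_rate(AreaSeries(times_h=t, area_mm2=base * scale))
        assert r1 == pytest.approx(r2)


class TestExploration:
    def test_static_organism_explored_equals_area(self, cal10):
        mask = np.zeros((60, 60), bool)
        mask[10:20, 10:30] = True
        s_e = exploration_series([mask] * 5, cal10, np.arange(5) * 60.0)
        s_a = area_series([mask] * 5, cal10, np.arange(5) * 60.0)
        assert np.allclose(s_e.explored_mm2, s_a.area_mm2)

    def test_translating_disc_union(self, cal10):
        # disc hops by its own diameter each frame: k disjoint discs
        k, r = 10, 10.0
        spec = phantom.PhantomSpec(
            kind="growing_disk", shape=(120, 320), disk_radius0=r,
            disk_velocity=(0.0, 2 * r), n_frames=k, interval_s=3600.0,
            noise_sigma=0.0, seed=2, antialias=False,
        )
        series, _ = phantom.make_growing_disk_series(spec, center=(60.0, 20.0))
        masks = growth.segment_series(series)
        s = exploration_series(masks, cal10, series.timestamps)
        union_oracle = np.logical_or.reduce(masks).sum() * 1e-4
        assert s.explored_mm2[-1] == pytest.approx(union_oracle)
        analytic = k * np.pi * r**2 * 1e-4
        assert s.explored_mm2[-1] == pytest.approx(analytic, rel=0.03)

    def test_shrinking_organism_keeps_maximum(self, cal10):
        big = np.ones((40, 40), bool)
        small = np.zeros((40, 40), bool)
        small[:10, :10] = True
        s = exploration_series([big, small], cal10, np.array([0.0, 60.0]))
        assert s.explored_mm2[1] == s.explored_mm2[0]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_under_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        masks = [rng.random((16, 16)) < 0.3 for _ in range(6)]
        cal = ScaleCalibration(10.0)
        s = exploration_series(masks, cal, np.arange(6) * 60.0)
        assert np.all(np.diff(s.explored_mm2) >= 0)
        areas = area_series(masks, cal, np.arange(6) * 60.0)
        assert np.all(s.explored_mm2 >= areas.area_mm2 - 1e-12)


class TestExplorationRate:
    def test_simple_division(self):
        s = ExplorationSeries(times_h=np.array([0.0, 24.0]),
                              explored_mm2=np.array([0.0, 48.0]))
        assert exploration_rate(s) == pytest.approx(2.0)

    def test_zero_exploration(self):
        s = ExplorationSeries(times_h=np.array([0.0, 24.0]),
                              explored_mm2=np.array([0.0, 0.0]))
        assert exploration_rate(s) == 0.0

    def test_short_series_rejected(self):
        s = ExplorationSeries(times_h=np.array([0.0, 5.0]),
                              explored_mm2=np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            exploration_rate(s)


class TestInhibition:
    def test_single_treated_vs_control_mean(self):
        assert growth_inhibition(75.0, np.array([100.0]))[0] == \
            pytest.approx(-0.25)

    def test_treated_equals_control(self):
        assert growth_inhibition(100.0, np.array([100.0]))[0] == 0.0

    def test_mean_then_ratio(self):
        out = growth_inhibition(80.0, np.array([90.0, 110.0]))
        assert out[0] == pytest.approx(-0.20)

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            growth_inhibition(1.0, np.array([0.0]))


class TestDoseResponse:
    def test_exact_cubic_interpolation(self):
        c = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = fit_dose_response(c, c**3)
        assert np.allclose(fit.coefficients, [1, 0, 0, 0], atol=1e-9)

    def test_constant_response(self):
        c = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_dose_response(c, np.full(4, 0.2))
        assert fit.coefficients[-1] == pytest.approx(0.2)
        assert np.allclose(fit.coefficients[:-1], 0.0, atol=1e-9)

    def test_noisy_cubic_recovers_leading_coefficient(self):
        rng = np.random.default_rng(12)
        c = np.repeat(np.linspace(0, 2, 6), 4)
        true_lead = 0.05
        y = true_lead * c**3 + rng.normal(0, 0.02, c.size)
        fit = fit_dose_response(c, y)
        # 2σ of the coefficient's sampling spread under the generator
        se = 0.02 / np.sqrt(c.size)
        assert abs(fit.coefficients[0] - true_lead) < 20 * se

    def test_insufficient_distinct_doses_rejected(self):
        c = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            fit_dose_response(c, c)
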