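"""Spot detection, Gaussian fitting, unit calibration and counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seamfish.spots import (
    CalibrationError,
    DetectionParams,
    Spot,
    SpotSet,
    UnitCalibration,
    calibrate_unit,
    count_mrna,
    detect_spots,
    fit_amplitude,
)
from tests.conftest import render_gaussians_2d


def spotset(amplitudes):
    return SpotSet([Spot(y=10.0 * i, x=5.0, amplitude=float(a), sigma=1.3)
                    for i, a in enumerate(amplitudes)])


class TestDetection:
    def test_all_zero_image_yields_no_spots(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert len(detect_spots(np.zeros((30, 30)))) == 0

    def test_non_finite_pixels_rejected(self):
        img = np.ones((20, 20))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_spots(img)

    def test_five_rendered_gaussians_recovered_subpixel(self):
        truth = [(10.2, 12.7), (11.0, 40.3), (30.6, 25.1), (42.8, 10.4),
                 (44.1, 44.9)]
        img = render_gaussians_2d(
            (55, 55), [(y, x, 200.0, 1.5) for y, x in truth], background=10.0
        )
        spots = detect_spots(img, DetectionParams(log_sigma=1.3))
        assert len(spots) == 5
        det = spots.positions()
        for y, x in truth:
            d = np.sqrt(((det - [y, x]) ** 2).sum(axis=1)).min()
            assert d < 0.5

    def test_two_equal_spots_one_px_apart_merge_to_one(self):
        img = render_gaussians_2d(
            (31, 31), [(15.0, 14.5, 150.0, 1.3), (15.0, 15.5, 150.0, 1.3)],
            background=5.0,
        )
        spots = detect_spots(img, DetectionParams(min_separation=3.0))
        assert len(spots) == 1

    def test_resolved_pair_merged_when_within_min_separation(self):
        """Two bimodally resolvable spots 2.5 px apart are still merged
        (brighter kept) when min separation is 3 px."""
        img = render_gaussians_2d(
            (31, 31), [(15.0, 13.75, 150.0, 0.8), (15.0, 16.25, 120.0, 0.8)],
            background=5.0,
        )
        loose = detect_spots(img, DetectionParams(log_sigma=0.8,
                                                  min_separation=1.0))
        merged = detect_spots(img, DetectionParams(log_sigma=0.8,
                                                   min_separation=3.0))
        assert len(loose) == 2
        assert len(merged) == 1
        assert merged[0].x < 15.0  # the brighter, left spot won

    def test_detection_is_translation_equivariant(self):
        base = [(12.4, 14.2), (25.7, 30.1), (38.9, 18.6)]
        shift = (3, 5)
        img_a = render_gaussians_2d(
            (60, 60), [(y, x, 180.0, 1.3) for y, x in base], background=8.0
        )
        img_b = render_gaussians_2d(
            (60, 60),
            [(y + shift[0], x + shift[1], 180.0, 1.3) for y, x in base],
            background=8.0,
        )
        params = DetectionParams(threshold=20.0)
        pos_a = np.sort(detect_spots(img_a, params).positions(), axis=0)
        pos_b = np.sort(detect_spots(img_b, params).positions(), axis=0)
        np.testing.assert_allclose(pos_b - pos_a, np.tile(shift, (3, 1)),
                                   atol=0.05)

    @given(st.floats(min_value=10.0, max_value=2000.0))
    @settings(max_examples=20, deadline=None)
    def test_raising_threshold_never_adds_spots(self, thr):
        rng = np.random.default_rng(1234)
        img = render_gaussians_2d(
            (50, 50),
            [(12.0, 12.0, 400.0, 1.3), (30.0, 35.0, 150.0, 1.3),
             (40.0, 12.0, 60.0, 1.3)],
            background=10.0,
        )
        img = rng.poisson(img).astype(float)
        n_low = len(detect_spots(img, DetectionParams(threshold=5.0)))
        n_hi = len(detect_spots(img, DetectionParams(threshold=5.0 + thr)))
        assert n_hi <= n_low

    def test_3d_mode_recovers_axial_position(self):
        zz, yy, xx = np.mgrid[0:15, 0:30, 0:30].astype(float)
        img = 10.0 + 300.0 * np.exp(
            -((zz - 7.3) ** 2) / (2 * 2.0**2)
            - ((yy - 14.6) ** 2 + (xx - 17.2) ** 2) / (2 * 1.3**2)
        )
        spots = detect_spots(img, DetectionParams(mode="3d", threshold=30.0))
        assert len(spots) == 1
        assert abs(spots[0].z - 7.3) < 1.0
        assert abs(spots[0].y - 14.6) < 0.5


class TestFitAmplitude:
    def test_noiseless_gaussian_fit_recovers_amplitude(self):
        img = render_gaussians_2d((25, 25), [(12.3, 11.6, 100.0, 1.3)],
                                  background=7.0)
        spot = fit_amplitude(img, 12, 12, DetectionParams())
        assert spot.amplitude == pytest.approx(100.0, rel=0.01)
        assert spot.background == pytest.approx(7.0, abs=0.5)
        assert spot.sigma == pytest.approx(1.3, rel=0.02)

    def test_poisson_replicates_mean_amplitude_within_ten_percent(self):
        rng = np.random.default_rng(99)
        base = render_gaussians_2d((25, 25), [(12.0, 12.0, 100.0, 1.3)],
                                   background=10.0)
        amps = []
        for _ in range(100):
            noisy = rng.poisson(base).astype(float)
            spot = fit_amplitude(noisy, 12, 12, DetectionParams())
            if not spot.flags:
                amps.append(spot.amplitude)
        assert np.mean(amps) == pytest.approx(100.0, rel=0.10)

    def test_window_clipped_by_border_flags_edge(self):
        img = render_gaussians_2d((25, 25), [(2.0, 12.0, 100.0, 1.3)],
                                  background=5.0)
        spot = fit_amplitude(img, 2, 12, DetectionParams())
        assert "edge" in spot.flags
        assert not spot.ok_for_calibration


class TestCalibration:
    def test_unit_is_mean_of_five_dimmest(self):
        cal = calibrate_unit(spotset([90, 95, 100, 105, 110, 300, 520]))
        assert cal.unit_amplitude == pytest.approx(100.0)
        assert cal.n_spots_used == 5

    def test_identical_amplitudes(self):
        assert calibrate_unit(spotset([50.0] * 7)).unit_amplitude == 50.0

    def test_too_few_spots_raises_unless_overridden(self):
        with pytest.raises(CalibrationError):
            calibrate_unit(spotset([80, 90, 100]))
        cal = calibrate_unit(spotset([80, 90, 100]), allow_fewer=True)
        assert cal.unit_amplitude == pytest.approx(90.0)
        assert cal.n_spots_used == 3

    def test_flagged_spots_excluded_from_calibration(self):
        spots = spotset([10, 90, 95, 100, 105, 110])
        spots[0].flags.add("edge")
        assert calibrate_unit(spots).unit_amplitude == pytest.approx(100.0)


class TestCounting:
    @pytest.mark.parametrize(
        "amplitude,expected",
        [(500.0, 5), (100.0, 1), (40.0, 1), (249.0, 2), (250.0, 3)],
    )
    def test_units_round_half_up_with_floor_one(self, amplitude, expected):
        cal = UnitCalibration(unit_amplitude=100.0, unit_integrated=1000.0)
        out = count_mrna(spotset([amplitude]), cal)
        assert out[0].units == expected

    def test_integrated_metric_uses_gaussian_volume(self):
        spots = spotset([100.0])
        unit_int = spots[0].integrated_intensity / 3.0
        cal = UnitCalibration(unit_amplitude=33.0, unit_integrated=unit_int)
        out = count_mrna(spots, cal, metric="integrated")
        assert out[0].units == 3

    def test_non_positive_unit_rejected(self):
        with pytest.raises(CalibrationError):
            UnitCalibration(unit_amplitude=0.0, unit_integrated=1.0)

    def test_count_mrna_does_not_mutate_input(self):
        spots = spotset([100.0])
        cal = UnitCalibration(unit_amplitude=100.0, unit_integrated=1.0)
        count_mrna(spots, cal)
        assert spots[0].units is None


class TestSpotSetRoundTrip:
    def test_dataframe_round_trip(self):
        spots = spotset([100.0, 200.0])
        spots[1].flags.add("edge")
        spots[0].units = 1
        back = SpotSet.from_dataframe(spots.to_dataframe())
        assert len(back) == 2
        assert back[0].units == 1
        assert back[1].flags == {"edge"}


def test_end_to_end_recovery_on_default_scene(quantified_scene):
    """On a rendered default embryo the calibrated unit lands within 10%
    of the generator's single-mRNA amplitude and per-cell totals within
    10% median relative error (parameter-recovery oracle)."""
    from seamfish.evaluate import match_spots, per_cell_unit_errors

    params, truth, table, counts, spots, cal, unassigned = quantified_scene
    assert abs(cal.unit_amplitude - params.unit_amplitude) < 0.10 * params.unit_amplitude
    errs = per_cell_unit_errors({c.cell_id: c.total for c in counts}, truth)
    assert np.median(errs) <= 0.10
    m = match_spots(spots, truth, tol_px=1.0)
    assert m.recall >= 0.95 and m.precision >= 0.95
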