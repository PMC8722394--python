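"""Band profiles, nuclear eviction, junction peak calling."""

import numpy as np
import pytest
from shapely.geometry import box

from seamfish.profiles import (
    PeakParams,
    ProfileTrace,
    evict_nuclear_signal,
    extract_band_profile,
    locate_junctions,
    peak_overlap_summary,
)


def make_trace(n=30, **channels):
    base = {"smFISH": np.zeros(n), "junction-GFP": np.zeros(n),
            "AJM-1": np.zeros(n), "DAPI": np.zeros(n)}
    base.update({k: np.asarray(v, dtype=float) for k, v in channels.items()})
    return ProfileTrace(positions=np.arange(n, dtype=float), channels=base)


def gaussian_bumps(n, centers, amp=100.0, sigma=1.5, base=5.0):
    x = np.arange(n, dtype=float)
    out = np.full(n, base)
    for c in centers:
        out += amp * np.exp(-((x - c) ** 2) / (2 * sigma**2))
    return out


class TestExtractBand:
    def test_uniform_image_gives_flat_trace(self):
        img = np.full((2, 20, 40), 7.0)
        trace = extract_band_profile(img, box(5, 5, 30, 12),
                                     channel_names=["a", "b"])
        for name in ("a", "b"):
            np.testing.assert_allclose(trace.channels[name], 7.0)

    def test_vertical_stripe_peaks_at_its_column(self):
        img = np.ones((1, 20, 40))
        img[0, :, 17] = 50.0
        trace = extract_band_profile(img, box(5, 5, 30, 12),
                                     channel_names=["a"])
        c = trace.channels["a"]
        assert trace.positions[np.nanargmax(c)] == 17

    def test_band_outside_image_rejected(self):
        img = np.ones((1, 20, 20))
        with pytest.raises(ValueError):
            extract_band_profile(img, box(100, 100, 120, 110))

    def test_zero_width_band_rejected(self):
        img = np.ones((1, 20, 20))
        with pytest.raises(ValueError):
            extract_band_profile(img, box(5.2, 2, 5.4, 18), axis="x")

    def test_vertical_axis_profiles_along_y(self):
        img = np.ones((1, 30, 20))
        img[0, 9, :] = 40.0
        trace = extract_band_profile(img, box(2, 2, 18, 28), axis="y",
                                     channel_names=["a"])
        assert trace.positions[np.nanargmax(trace.channels["a"])] == 9

    def test_simulated_junction_columns_are_trace_maxima(self, default_scene):
        params, stack, rois, truth = default_scene
        trace = extract_band_profile(
            stack, rois.cells[0]["profile_band_apicobasal"]
        )
        ajm = trace.channels["AJM-1"]
        for jx in truth.junctions_x:
            i = int(jx - trace.positions[0])
            window = ajm[max(0, i - 2) : i + 3]
            assert np.nanmax(window) > 3 * np.nanmedian(ajm)


class TestEviction:
    def test_dna_below_threshold_leaves_trace_unchanged(self):
        trace = make_trace(DAPI=np.full(30, 5.0), smFISH=np.arange(30.0))
        out = evict_nuclear_signal(trace, dna_threshold=10.0)
        assert out.nuclear_spans == []
        np.testing.assert_array_equal(out.channels["smFISH"],
                                      trace.channels["smFISH"])

    def test_thresholded_bins_become_missing_exactly(self):
        dna = np.zeros(30)
        dna[8:13] = 100.0
        trace = make_trace(DAPI=dna, smFISH=np.full(30, 2.0))
        out = evict_nuclear_signal(trace, dna_threshold=50.0, dilate_bins=0)
        assert out.nuclear_spans == [(8.0, 12.0)]
        missing = np.isnan(out.channels["smFISH"])
        np.testing.assert_array_equal(np.nonzero(missing)[0], np.arange(8, 13))
        assert np.isfinite(out.channels["DAPI"]).all()
        np.testing.assert_array_equal(out.channels["AJM-1"],
                                      trace.channels["AJM-1"])

    def test_span_dilation_expands_by_requested_bins(self):
        dna = np.zeros(30)
        dna[10:12] = 100.0
        trace = make_trace(DAPI=dna)
        out = evict_nuclear_signal(trace, dna_threshold=50.0, dilate_bins=1)
        assert out.nuclear_spans == [(9.0, 12.0)]

    def test_eviction_is_idempotent_with_otsu(self, default_scene):
        params, stack, rois, _ = default_scene
        trace = extract_band_profile(
            stack, rois.cells[0]["profile_band_apicobasal"]
        )
        once = evict_nuclear_signal(trace)
        twice = evict_nuclear_signal(once)
        assert once.nuclear_spans == twice.nuclear_spans
        a, b = once.channels["smFISH"], twice.channels["smFISH"]
        np.testing.assert_array_equal(np.isnan(a), np.isnan(b))
        np.testing.assert_array_equal(a[~np.isnan(a)], b[~np.isnan(b)])

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ValueError):
            evict_nuclear_signal(make_trace(), dna_threshold=-1.0)

    def test_evicted_spans_cover_true_nuclei(self, default_scene):
        """Otsu-thresholded spans cover >= 95% of the bins where the band
        crosses a true nucleus (generator geometry oracle)."""
        params, stack, rois, _ = default_scene
        trace = extract_band_profile(
            stack, rois.cells[0]["profile_band_apicobasal"]
        )
        out = evict_nuclear_signal(trace)
        pos = out.positions
        covered = np.zeros(len(pos), dtype=bool)
        for lo, hi in out.nuclear_spans:
            covered |= (pos >= lo) & (pos <= hi)
        true_nuclear = np.zeros(len(pos), dtype=bool)
        for cell in rois:
            b = cell["nuclear"].bounds
            true_nuclear |= (pos >= b[0]) & (pos <= b[2])
        assert covered[true_nuclear].mean() >= 0.95


class TestJunctions:
    def test_two_rendered_peaks_recovered_within_one_px(self):
        trace = make_trace(n=21, **{"AJM-1": gaussian_bumps(21, [2.0, 18.0])})
        pos = locate_junctions(trace)
        assert len(pos) == 2
        np.testing.assert_allclose(pos, [2.0, 18.0], atol=1.0)

    def test_flat_trace_yields_empty_with_warning(self):
        trace = make_trace(n=15, **{"AJM-1": np.full(15, 3.0)})
        with pytest.warns(UserWarning, match="flat"):
            assert len(locate_junctions(trace)) == 0

    def test_calls_invariant_under_intensity_scaling(self):
        bumps = gaussian_bumps(40, [5.0, 20.0, 35.0], amp=80.0)
        a = locate_junctions(make_trace(n=40, **{"AJM-1": bumps}))
        b = locate_junctions(make_trace(n=40, **{"AJM-1": 13.7 * bumps}))
        np.testing.assert_allclose(a, b)

    def test_low_prominence_peaks_filtered(self):
        bumps = gaussian_bumps(40, [10.0], amp=100.0)
        bumps += gaussian_bumps(40, [30.0], amp=10.0, base=0.0)
        pos = locate_junctions(make_trace(n=40, **{"AJM-1": bumps}),
                               PeakParams(min_prominence_frac=0.2))
        assert len(pos) == 1

    def test_three_cells_give_four_junctions_at_cell_boundaries(
        self, profile_scene_small
    ):
        params, stack, rois, truth = profile_scene_small
        trace = extract_band_profile(
            stack, rois.cells[0]["profile_band_apicobasal"]
        )
        called = locate_junctions(trace)
        assert len(called) == len(truth.junctions_x) == params.n_cells + 1
        errors = np.abs(np.sort(called) - np.sort(truth.junctions_x))
        assert errors.max() <= 1.0

    def test_membrane_mrna_enriched_at_junction_bins(self, profile_scene_small):
        """With membrane-localized spots, junction-adjacent mRNA intensity
        exceeds mid-cell intensity at the trace level."""
        params, stack, rois, truth = profile_scene_small
        trace = extract_band_profile(
            stack, rois.cells[0]["profile_band_apicobasal"]
        )
        trace = evict_nuclear_signal(trace)
        mrna = trace.channels["smFISH"]
        pos = trace.positions
        near = np.zeros(len(pos), dtype=bool)
        for jx in truth.junctions_x:
            near |= np.abs(pos - jx) <= 3.0
        evicted = np.isnan(mrna)
        mid = ~near & ~evicted
        assert np.nanmean(mrna[near]) > np.nanmean(mrna[mid])


class TestNormalization:
    def test_per_trace_scaling_preserves_nans_and_range(self):
        from seamfish.profiles import normalize_per_trace

        mrna = gaussian_bumps(30, [10.0], amp=200.0, base=20.0)
        mrna[5:8] = np.nan
        trace = make_trace(n=30, smFISH=mrna,
                           DAPI=np.full(30, 9.0))
        out = normalize_per_trace(trace)
        scaled = out.channels["smFISH"]
        assert np.isnan(scaled[5:8]).all()
        assert np.nanmin(scaled) == 0.0 and np.nanmax(scaled) == 1.0
        assert (out.channels["DAPI"] == 0.0).all()
        # junction calls are unchanged by the scaling
        bumps = gaussian_bumps(30, [8.0, 22.0])
        t_raw = make_trace(n=30, **{"AJM-1": bumps})
        np.testing.assert_allclose(
            locate_junctions(t_raw),
            locate_junctions(normalize_per_trace(t_raw)),
        )


class TestPeakOverlap:
    def test_exact_overlap_is_one(self):
        bumps = gaussian_bumps(40, [8.0, 30.0])
        trace = make_trace(n=40, **{"AJM-1": bumps, "smFISH": bumps.copy(),
                                    "junction-GFP": bumps.copy()})
        locate_junctions(trace)
        summary = peak_overlap_summary(trace, tol_px=2.0)
        assert summary["mrna_peak_overlap"] == 1.0
        assert summary["protein_peak_overlap"] == 1.0

    def test_distant_peaks_score_zero(self):
        trace = make_trace(
            n=60,
            **{"AJM-1": gaussian_bumps(60, [10.0, 50.0]),
               "smFISH": gaussian_bumps(60, [30.0])},
        )
        locate_junctions(trace)
        summary = peak_overlap_summary(trace, tol_px=2.0)
        assert summary["mrna_peak_overlap"] == 0.0

    def test_no_peaks_reports_missing(self):
        trace = make_trace(n=30, **{"AJM-1": gaussian_bumps(30, [15.0])})
        locate_junctions(trace)
        summary = peak_overlap_summary(trace, tol_px=2.0)
        assert summary["mrna_peak_overlap"] is None

    def test_requires_junctions_called_first(self):
        with pytest.raises(ValueError, match="locate_junctions"):
            peak_overlap_summary(make_trace(), tol_px=2.0)

    def test_fraction_matches_brute_force_distance_check(self):
        rng = np.random.default_rng(4)
        n = 120
        junction_centers = [15.0, 55.0, 95.0]
        mrna_centers = sorted(rng.uniform(5, n - 5, 5))
        trace = make_trace(
            n=n,
            **{"AJM-1": gaussian_bumps(n, junction_centers),
               "smFISH": gaussian_bumps(n, mrna_centers)},
        )
        junctions = locate_junctions(trace)
        tol = 4.0
        summary = peak_overlap_summary(trace, tol_px=tol)
        # brute-force oracle over the *called* peak positions
        from seamfish.profiles import _find_channel_peaks

        peaks = _find_channel_peaks(trace.channels["smFISH"], trace.positions,
                                    PeakParams())
        expected = np.mean([
            min(abs(p - j) for j in junctions) <= tol for p in peaks
        ])
        assert summary["mrna_peak_overlap"] == pytest.approx(expected)


@pytest.fixture(scope="module")
def profile_scene_small():
    from seamfish import SceneParams, simulate_embryo
    from seamfish.experiments import PROFILE_SCENE

    params = SceneParams(seed=21, **PROFILE_SCENE)
    stack, rois, truth = simulate_embryo(params)
    return params, stack, rois, truth
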