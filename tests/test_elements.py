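"""Per-element analysis: smoothing, peak ROI, summaries, position derivation."""

import numpy as np
import pytest

from coilqa import synthetic as sy
from coilqa.combined import AnalysisConfig
from coilqa.elements import (
    OCTANT_LABELS,
    analyze_element_series,
    derive_element_position,
    locate_peak_roi,
    smooth_signal,
    summarize_peak_snr,
)
from coilqa.errors import AlignmentError, CoverageError, GeometryError


class TestSmoothing:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 5.0)
        np.testing.assert_allclose(smooth_signal(img), img)

    def test_impulse_becomes_unit_plateau(self):
        img = np.zeros((40, 40))
        img[20, 20] = 100.0
        sm = smooth_signal(img, window=10)
        # interior footprint of the 10x10 box holds 100/100 = 1.0
        assert sm[20, 20] == pytest.approx(1.0)
        assert sm.max() == pytest.approx(1.0)
        assert sm.sum() == pytest.approx(100.0)

    def test_matches_naive_sliding_window(self):
        """Brute-force double-loop oracle with replicate borders; the even
        window is anchored one pixel toward the top-left."""
        rng = np.random.default_rng(5)
        for window in (3, 10):
            img = rng.random((20, 20))
            lo = window // 2
            padded = np.pad(img, window, mode="edge")
            naive = np.empty_like(img)
            for i in range(20):
                for j in range(20):
                    naive[i, j] = padded[
                        i - lo + window : i - lo + 2 * window,
                        j - lo + window : j - lo + 2 * window,
                    ].mean()
            np.testing.assert_allclose(smooth_signal(img, window), naive, atol=1e-12)


class TestPeakRoi:
    def test_tie_broken_lexicographically(self):
        mask = np.ones((64, 64), bool)
        img = np.zeros((64, 64))
        img[40, 40] = img[20, 30] = 50.0  # two equal maxima
        # window 1 disables smoothing so the tie occurs at the raw maxima
        peak, _ = locate_peak_roi(img, mask, roi_radius=5, smoothing_window=1)
        assert peak == (20, 30)

    def test_roi_stays_inside_phantom(self, torso_element_metrics, design):
        disc = sy.phantom_disc(design)
        for metrics in torso_element_metrics.values():
            for m in metrics:
                r, c = m.peak_center
                assert disc[r, c]
                # full 5-px ROI inside the disc
                rr, cc = np.ogrid[: disc.shape[0], : disc.shape[1]]
                roi = (rr - r) ** 2 + (cc - c) ** 2 <= m.roi.radius**2
                assert np.all(disc[roi])

    def test_peak_near_ground_truth_sensitivity_maximum(self, torso_elements, torso_element_metrics):
        _, _, truth = torso_elements
        for element in truth.elements:
            metrics = torso_element_metrics[element.label]
            best = max(metrics, key=lambda m: m.mean_peak_signal)
            true_rc = truth.peak_position_px(element)
            dist = np.hypot(best.peak_center[0] - true_rc[0], best.peak_center[1] - true_rc[1])
            # truth sits on the rim; the detected peak is pulled inside by
            # the eroded-mask constraint (~6 px) plus noise jitter
            assert dist < 12

    def test_tiny_mask_raises(self):
        mask = np.zeros((32, 32), bool)
        mask[10:13, 10:13] = True
        with pytest.raises(GeometryError):
            locate_peak_roi(np.ones((32, 32)), mask, roi_radius=5)

    def test_default_peak_roi_radius_is_5p86_mm(self, design):
        assert 5 * design.pixel_spacing == pytest.approx(5.86, abs=0.005)


class TestAnalyzeElements:
    def test_noise_sd_identical_for_single_element_sos(self, small_design):
        """With one element the sum-of-squares by-product is the element
        itself, so the transferred-ROI noise SD matches exactly."""
        uncombined, sos, _ = sy.make_element_series(
            small_design, [sy.ElementModel(label="VAP1")], sy.NoiseModel(), seed=41
        )
        metrics = analyze_element_series(uncombined, sos)["VAP1"]
        from coilqa.combined import analyze_combined_series

        sos_metrics = analyze_combined_series(sos)
        for m, s in zip(metrics, sos_metrics):
            assert m.noise_sd == pytest.approx(s.noise_sd)

    def test_dead_element_separates_from_healthy(self, design):
        elements = sy.apply_fault(sy.default_elements("torso"), "VAS1", "dead")
        uncombined, sos, _ = sy.make_element_series(design, elements, sy.NoiseModel(), seed=42)
        metrics = analyze_element_series(uncombined, sos)
        assert all(m.snr < 5 for m in metrics["VAS1"])
        for label in ("VAP1", "VPP2", "VPS3"):
            assert max(m.snr for m in metrics[label]) > 20

    def test_absent_channel_has_negligible_snr(self, design):
        """Head/Neck VAP3/VPP3 channels record noise but no signal."""
        elements = sy.default_elements("headneck")
        uncombined, sos, _ = sy.make_element_series(design, elements, sy.NoiseModel(), seed=43)
        metrics = analyze_element_series(uncombined, sos)
        for label in ("VAP3", "VPP3"):
            assert all(m.snr < 3 for m in metrics[label])
            assert derive_element_position(metrics[label]) == ("undetectable", None)

    def test_slice_mismatch_raises(self, small_design):
        uncombined, sos, _ = sy.make_element_series(
            small_design, [sy.ElementModel(label="VAP1")], sy.NoiseModel(), seed=44
        )
        with pytest.raises(AlignmentError):
            analyze_element_series(uncombined, sos[:-1])

    def test_transferred_roi_consistency(self, torso_element_metrics):
        """All elements of one slice share the identical noise ROI."""
        by_slice = {}
        for metrics in torso_element_metrics.values():
            for m in metrics:
                by_slice.setdefault(m.slice_location, set()).add(m.phantom_center)
        assert all(len(centers) == 1 for centers in by_slice.values())

    def test_peak_signal_bounded_by_image_maximum(self, torso_elements, torso_element_metrics):
        uncombined, _, _ = torso_elements
        for label, pairs in uncombined.items():
            by_loc = {p.meta.slice_location: p for p in pairs}
            for m in torso_element_metrics[label]:
                assert m.mean_peak_signal <= by_loc[m.slice_location].signal_pixels.max()


class TestSummaries:
    def test_mean_and_sd_arithmetic(self):
        from coilqa.elements import ElementSliceMetrics
        from coilqa.segmentation import CircularRoi

        metrics = {
            "VAP1": [
                ElementSliceMetrics("VAP1", loc, 5.0, (10, 10), snr * 5.0, snr, (0, 0),
                                    CircularRoi((10, 10), 5))
                for loc, snr in [(110.0, 60.0), (130.0, 62.0), (150.0, 64.0), (90.0, 70.0)]
            ]
        }
        (summary,) = summarize_peak_snr(metrics)
        assert summary.peak_snr_mean == pytest.approx(62.0)
        assert summary.peak_snr_sd == pytest.approx(2.0)
        assert summary.slices_used == (110.0, 130.0, 150.0)

    def test_inferior_groups_use_negative_slices(self, torso_element_metrics):
        summaries = {s.element_label: s for s in summarize_peak_snr(torso_element_metrics)}
        assert summaries["VAS2"].slices_used == (-110.0, -130.0, -150.0)
        assert summaries["VPS1"].slices_used == (-110.0, -130.0, -150.0)
        assert summaries["VAP1"].slices_used == (110.0, 130.0, 150.0)

    def test_missing_required_slices_raises(self, small_design):
        uncombined, sos, _ = sy.make_element_series(
            small_design, [sy.ElementModel(label="VAP1")], sy.NoiseModel(), seed=45
        )
        metrics = analyze_element_series(uncombined, sos)
        with pytest.raises(CoverageError):
            summarize_peak_snr(metrics)  # 4-slice stack has no ±110/130/150 mm


class TestPositionDerivation:
    def test_octants_and_axial_signs(self, torso_elements, torso_element_metrics):
        _, _, truth = torso_elements
        for element in truth.elements:
            axial, octant = derive_element_position(torso_element_metrics[element.label])
            assert axial == ("superior" if element.axial_center >= 0 else "inferior")
            expected_octant = int(((element.in_plane_angle + 22.5) % 360) // 45)
            assert octant == expected_octant, (element.label, OCTANT_LABELS[octant])
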