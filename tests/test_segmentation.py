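import math

import numpy as np
import pytest

import cometkit as ck
from cometkit.errors import (DegenerateHistogramError, EmptySegmentationError,
                             GeometryError)

from conftest import roi_around


# ---------------------------------------------------------------------------
# Brute-force threshold oracles (pure-python, independent of the package)
# ---------------------------------------------------------------------------

def otsu_bruteforce(hist):
    """Exhaustive between-class-variance scan with plateau-midpoint ties."""
    total = sum(hist)
    best, tied = -1.0, []
    for t in range(len(hist) - 1):
        w0 = sum(hist[:t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * hist[i] for i in range(t + 1)) / w0
        mu1 = sum(i * hist[i] for i in range(t + 1, len(hist))) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best * (1 + 1e-12):
            best, tied = v, [t]
        elif v >= best * (1 - 1e-12):
            tied.append(t)
    return float(math.floor(sum(tied) / len(tied)))


def triangle_bruteforce(hist):
    """Per-bin perpendicular point-to-line distance scan."""
    nonempty = [i for i, h in enumerate(hist) if h > 0]
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    lo, hi = nonempty[0], nonempty[-1]
    end = hi if hi - peak >= peak - lo else lo
    a, b = min(peak, end), max(peak, end)
    dx, dy = end - peak, hist[end] - hist[peak]
    norm = math.hypot(dx, dy)
    best, best_t = -1.0, None
    for t in range(a, b + 1):
        if t in (peak, end):
            continue
        d = abs(dy * (t - peak) - dx * (hist[t] - hist[peak])) / norm
        if d > best * (1 + 1e-12) or (
                d >= best * (1 - 1e-12) and best_t is not None
                and abs(t - peak) < abs(best_t - peak)):
            best, best_t = d, t
    return float(best_t if best_t is not None else min(peak, end))


def random_histograms(n, rng, bins=256):
    """Mixture-of-two-gaussians histograms: the comet-assay ROI regime."""
    for _ in range(n):
        bg_mu = rng.uniform(10, 80)
        fg_mu = rng.uniform(bg_mu + 40, 250)
        n_bg = int(rng.integers(500, 20000))
        n_fg = int(rng.integers(50, 5000))
        vals = np.concatenate([
            rng.normal(bg_mu, rng.uniform(2, 12), n_bg),
            rng.normal(fg_mu, rng.uniform(5, 30), n_fg)])
        hist, _ = np.histogram(np.clip(vals, 0, bins - 1), bins=bins,
                               range=(0, bins))
        if np.count_nonzero(hist) >= 3:
            yield hist.astype(int)


class TestThresholds:
    def test_otsu_two_spikes_thresholds_strictly_between(self):
        hist = np.zeros(256, dtype=int)
        hist[10] = 500
        hist[200] = 500
        t = ck.otsu_threshold(hist)
        assert 10 < t < 200

    def test_otsu_uniform_histogram_near_midpoint(self):
        hist = np.ones(256, dtype=int)
        t = ck.otsu_threshold(hist)
        assert abs(t - 127.5) <= 2
        assert t == otsu_bruteforce(list(hist))

    def test_otsu_matches_bruteforce_on_skewed_mass(self):
        hist = np.zeros(256, dtype=int)
        hist[50] = 900
        hist[180] = 100
        assert ck.otsu_threshold(hist) == otsu_bruteforce(list(hist))

    def test_otsu_matches_bruteforce_on_random_histograms(self):
        rng = np.random.default_rng(123)
        for hist in random_histograms(60, rng):
            assert ck.otsu_threshold(hist) == otsu_bruteforce(list(hist))

    def test_triangle_spike_plus_tail(self):
        hist = np.zeros(256, dtype=int)
        hist[30] = 1000
        hist[31:251] = np.linspace(60, 1, 220).astype(int)
        t = ck.triangle_threshold(hist)
        assert 30 < t < 251
        assert t == triangle_bruteforce(list(hist))

    def test_triangle_symmetric_histogram_takes_bright_side(self):
        hist = np.zeros(256, dtype=int)
        center = 128
        for off in range(-50, 51):
            hist[center + off] = 1000 - 15 * abs(off)
        t = ck.triangle_threshold(hist)
        assert t > center  # tie on side lengths resolves to the bright side

    def test_triangle_two_bin_histogram(self):
        hist = np.zeros(256, dtype=int)
        hist[20] = 100
        hist[200] = 10
        t = ck.triangle_threshold(hist)
        assert 20 <= t <= 200

    def test_triangle_matches_bruteforce_on_random_histograms(self):
        rng = np.random.default_rng(321)
        for hist in random_histograms(60, rng):
            assert ck.triangle_threshold(hist) == triangle_bruteforce(list(hist))

    def test_combined_is_arithmetic_mean(self):
        rng = np.random.default_rng(7)
        for hist in random_histograms(10, rng):
            expected = 0.5 * (ck.otsu_threshold(hist)
                              + ck.triangle_threshold(hist))
            assert ck.combined_threshold(hist) == expected

    @pytest.mark.parametrize("fn", [ck.otsu_threshold, ck.triangle_threshold,
                                    ck.combined_threshold])
    def test_degenerate_histograms_raise(self, fn):
        single = np.zeros(256, dtype=int)
        single[40] = 100
        with pytest.raises(DegenerateHistogramError):
            fn(single)
        with pytest.raises(DegenerateHistogramError):
            fn(np.zeros(256, dtype=int))


class TestSegmentRoi:
    def test_head_tail_partition_identities(self, noiseless_truth):
        truth = noiseless_truth
        for cid in truth.comet_mask.ids:
            roi = roi_around(truth.comet_mask.object_mask(cid))
            seg = ck.segment_roi(truth.image, roi, comet_id=int(cid))
            np.testing.assert_array_equal(seg.head_mask | seg.tail_mask,
                                          seg.comet_mask)
            assert not (seg.head_mask & seg.tail_mask).any()
            seg.validate()

    @pytest.mark.parametrize("modality", ["otsu", "triangle", "average"])
    def test_undamaged_comet_has_empty_tail(self, modality):
        truth = ck.generate_dataset(n_images=1, comets_per_image=(4, 6),
                                    class_mix=(1, 0, 0, 0, 0),
                                    image_shape=(400, 500),
                                    noise={"gaussian_sd": 0.0}, seed=2)[0]
        for cid in truth.comet_mask.ids:
            gt = truth.comet_mask.object_mask(cid)
            seg = ck.segment_roi(truth.image, roi_around(gt),
                                 ck.ThresholdSettings(modality=modality))
            assert not seg.tail_mask.any()
            assert ck.pairwise_ji(seg.head_mask, seg.comet_mask) == 1.0

    def test_damaged_comet_tail_percent_near_truth(self, single_comet):
        params, image, comet_m, head_m = single_comet
        roi = roi_around(comet_m)
        seg = ck.segment_roi(image, roi)
        rec = ck.comet_features(image, seg)
        assert rec.values["tail_percent_dna"] == pytest.approx(50, abs=10)
        # head centred on the rendered head, tail on the tail side
        hr, hc = np.nonzero(seg.head_mask)
        gt_hr, gt_hc = np.nonzero(head_m)
        assert math.hypot(hr.mean() - gt_hr.mean(), hc.mean() - gt_hc.mean()) < 6

    def test_comet_scale_monotone_in_area(self, single_comet):
        _, image, comet_m, _ = single_comet
        roi = roi_around(comet_m)
        areas = []
        for scale in (1.0, 1.2, 1.5):
            seg = ck.segment_roi(image, roi,
                                 ck.ThresholdSettings(comet_scale=scale))
            areas.append(seg.comet_mask.sum())
        assert areas[0] >= areas[1] >= areas[2]

    def test_dilation_monotone_in_area(self, single_comet):
        _, image, comet_m, _ = single_comet
        roi = roi_around(comet_m)
        areas = [ck.segment_roi(image, roi,
                                ck.ThresholdSettings(dilation_radius=r)
                                ).comet_mask.sum() for r in (0, 2, 5)]
        assert areas[0] <= areas[1] <= areas[2]

    def test_empty_roi_raises(self):
        pixels = np.zeros((50, 50), dtype=np.uint8)
        pixels[10, 10] = 200  # contrast far from the ROI
        image = ck.IntensityImage(pixels)
        roi = ck.Roi("circle", center=(40, 40), radius=5)
        with pytest.raises((EmptySegmentationError, DegenerateHistogramError)):
            ck.segment_roi(image, roi)

    def test_roi_fully_outside_image_is_geometry_error(self, single_comet):
        _, image, _, _ = single_comet
        roi = ck.Roi("circle", center=(-100, -100), radius=3)
        with pytest.raises(GeometryError):
            ck.segment_roi(image, roi)


class TestRasterizeContour:
    def test_square_polygon_area_is_boundary_inclusive(self, single_comet):
        _, image, comet_m, _ = single_comet
        rr, cc = np.nonzero(comet_m)
        r0, c0 = int(rr.mean()) - 5, int(cc.mean()) - 5
        verts = np.array([[r0, c0], [r0, c0 + 9], [r0 + 9, c0 + 9], [r0 + 9, c0]])
        seg = ck.rasterize_contour(verts, image)
        assert seg.comet_mask.sum() == 100

    def test_triangle_area_close_to_analytic(self, single_comet):
        _, image, comet_m, _ = single_comet
        rr, cc = np.nonzero(comet_m)
        r0, c0 = int(rr.mean()), int(cc.mean())
        verts = np.array([[r0 - 10, c0], [r0 + 10, c0 - 10], [r0 + 10, c0 + 10]])
        seg = ck.rasterize_contour(verts, image)
        analytic = 0.5 * 20 * 20
        # one pixel-row of slack on a 20-px base
        assert abs(seg.comet_mask.sum() - analytic) <= 25

    def test_self_intersecting_polygon_rejected(self, single_comet):
        _, image, _, _ = single_comet
        bowtie = np.array([[10, 10], [30, 30], [10, 30], [30, 10]])
        with pytest.raises(GeometryError):
            ck.rasterize_contour(bowtie, image)

    def test_polygon_over_background_is_empty_segmentation(self, single_comet):
        _, image, comet_m, _ = single_comet
        # a corner far from the rendered comet
        verts = np.array([[1, 1], [1, 8], [8, 8], [8, 1]])
        assert not comet_m[:10, :10].any()
        with pytest.raises(EmptySegmentationError):
            ck.rasterize_contour(verts, image)


class TestDetectComets:
    def test_detects_most_well_separated_comets(self):
        truth = ck.generate_dataset(n_images=1, comets_per_image=(30, 30),
                                    seed=9)[0]
        rois = ck.detect_comets(truth.image)
        centers = [p.center for p in truth.params]
        n_single = 0
        for roi in rois:
            hits = [c for c in centers
                    if math.hypot(c[0] - roi.center[0], c[1] - roi.center[1])
                    <= roi.radius]
            if len(hits) == 1:
                n_single += 1
        assert n_single >= 27

    def test_blank_image_yields_no_rois(self):
        image = ck.IntensityImage(np.full((100, 100), 10, dtype=np.uint8))
        assert ck.detect_comets(image) == []

    def test_border_touching_object_excluded_by_default(self):
        pixels = np.full((120, 120), 10, dtype=np.uint8)
        pixels[0:20, 50:70] = 200     # touches the top border
        pixels[60:80, 50:70] = 200    # interior object
        image = ck.IntensityImage(pixels)
        rois = ck.detect_comets(image)
        assert len(rois) == 1
        assert abs(rois[0].center[0] - 69.5) < 2

    def test_pluggable_detector_is_used(self, single_comet):
        _, image, _, _ = single_comet
        sentinel = [ck.Roi("circle", center=(1, 1), radius=2)]
        settings = ck.DetectorSettings(detector=lambda img, s: sentinel)
        assert ck.detect_comets(image, settings) is sentinel
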