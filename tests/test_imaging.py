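"""Triangle thresholding, mask geometry, well assignment, and measurement."""

import math

import numpy as np
import pytest

from obscpipe import imaging, simulate
from obscpipe.imaging import (MaskSet, PlateImage, assign_wells, bisect_mask,
                              ingest_masks, measure_d1t, measure_pi,
                              measure_tumor_signal, segment_slices_fallback,
                              triangle_threshold)


def brute_force_triangle(values, n_bins=256):
    """Independent oracle: enumerate every bin's perpendicular distance to the
    peak-to-tail line and take the argmax, offset one bin toward the tail."""
    v = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(counts))
    nz = np.nonzero(counts)[0]
    tail = int(nz[-1]) if (nz[-1] - peak) >= (peak - nz[0]) else int(nz[0])
    p = np.array([peak, counts[peak]], dtype=float)
    t = np.array([tail, counts[tail]], dtype=float)
    norm = np.hypot(*(t - p))
    best, best_d = peak, -1.0
    lo, hi = min(peak, tail), max(peak, tail)
    for i in range(lo, hi + 1):
        q = np.array([i, counts[i]], dtype=float)
        d = abs((t[0] - p[0]) * (p[1] - q[1]) - (p[0] - q[0]) * (t[1] - p[1])) / norm
        if d > best_d:
            best, best_d = i, d
    step = 1 if tail > peak else -1
    return float(centers[int(np.clip(best + step, 0, n_bins - 1))])


def _mixture_sample(rng, n_bg=5000, n_fg=100, fg_level=200.0):
    bg = np.abs(rng.normal(5.0, 2.0, n_bg))
    fg = rng.normal(fg_level, 10.0, n_fg)
    return np.concatenate([bg, fg])


class TestTriangleThreshold:
    def test_agrees_with_exhaustive_bin_search(self):
        rng = np.random.default_rng(123)
        for i in range(25):
            sample = _mixture_sample(rng, n_fg=rng.integers(10, 500),
                                     fg_level=rng.uniform(50, 250))
            result = triangle_threshold(sample)
            assert float(result) == brute_force_triangle(sample)

    def test_two_level_histogram(self):
        values = np.zeros(10000)
        values[:100] = 255.0
        thr = triangle_threshold(values)
        assert 0.0 < float(thr) < 255.0
        assert np.all(values[values > float(thr)] == 255.0)
        assert (values > float(thr)).sum() == 100

    def test_constant_sample_flagged_degenerate(self):
        thr = triangle_threshold(np.full(50, 7.0))
        assert thr.degenerate
        assert float(thr) == 7.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            triangle_threshold(np.array([]))


def ellipse_mask(shape, center, axes, angle_deg):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    t = math.radians(angle_deg)
    dx, dy = cc - center[1], rr - center[0]
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


class TestBisectMask:
    @pytest.mark.parametrize("angle", [0.0, 37.0, -20.0, 80.0])
    def test_hemisphere_areas_equal_and_line_through_centroid(self, angle):
        mask = ellipse_mask((300, 300), (150, 150), (100, 50), angle)
        pair = bisect_mask(mask)
        a_left, a_right = pair.left.sum(), pair.right.sum()
        assert abs(a_left - a_right) / mask.sum() < 0.02
        mid = np.add(pair.line_start, pair.line_end) / 2.0
        centroid = np.array(np.nonzero(mask)).mean(axis=1)
        assert np.hypot(*(mid - centroid)) < 1.0

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            mask = ellipse_mask((200, 200), (100 + rng.uniform(-20, 20),
                                             100 + rng.uniform(-20, 20)),
                                (rng.uniform(30, 70), rng.uniform(15, 30)),
                                rng.uniform(-90, 90))
            # roughen the boundary so masks are not perfect ellipses
            noise = rng.random(mask.shape) < 0.002
            mask = mask ^ (noise & mask)
            pair = bisect_mask(mask)
            assert not (pair.left & pair.right).any()
            assert ((pair.left | pair.right) == mask).all()

    def test_circle_uses_deterministic_vertical_split(self):
        mask = ellipse_mask((201, 201), (100, 100), (60, 60), 0.0)
        pair = bisect_mask(mask)
        assert abs(int(pair.left.sum()) - int(pair.right.sum())) / mask.sum() < 0.02
        # vertical dividing line: left hemisphere strictly in lower columns
        assert pair.left[:, :100].sum() > 0 and pair.left[:, 101:].sum() == 0

    def test_along_axis_switch_splits_lengthwise(self):
        # horizontal ellipse: 'along' divides top/bottom instead of left/right
        mask = ellipse_mask((200, 300), (100, 150), (100, 40), 0.0)
        pair = bisect_mask(mask, axis="along")
        assert not (pair.left & pair.right).any()
        assert ((pair.left | pair.right) == mask).all()
        # halves sit above/below the center (the rasterized box may tilt ~1 deg)
        assert np.nonzero(pair.left)[0].mean() < 90
        assert np.nonzero(pair.right)[0].mean() > 110
        assert abs(int(pair.left.sum()) - int(pair.right.sum())) / mask.sum() < 0.02

    def test_tiny_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValueError):
            bisect_mask(mask)


class TestIngestAndWells:
    def test_labels_preserved_verbatim(self):
        labels = np.zeros((50, 50), dtype=np.int32)
        labels[5:15, 5:15] = 3
        labels[30:40, 30:45] = 7
        masks = ingest_masks(labels)
        assert masks.labels == [3, 7]
        assert (masks.mask(3) == (labels == 3)).all()

    def test_shape_mismatch_and_float_labels_rejected(self):
        labels = np.zeros((50, 50), dtype=np.int32)
        labels[1, 1] = 1
        with pytest.raises(ValueError):
            ingest_masks(labels, image_shape=(60, 60))
        with pytest.raises(ValueError):
            ingest_masks(np.full((10, 10), 0.5))

    def test_centroid_grid_arithmetic(self):
        labels = np.zeros((100, 300), dtype=np.int32)
        labels[28:32, 58:62] = 1  # centroid (29.5, 59.5) -> cell (0, 0) in 2x3
        masks = assign_wells(ingest_masks(labels), (2, 3))
        assert masks.wells[1] == (0, 0)

    def test_top_before_bottom_within_well(self):
        labels = np.zeros((400, 200), dtype=np.int32)
        labels[95:105, 90:110] = 2   # row ~100
        labels[295:305, 90:110] = 1  # row ~300
        masks = assign_wells(ingest_masks(labels), (1, 1))
        assert masks.positions[2] == "top"
        assert masks.positions[1] == "bottom"
        assert list(masks.iter_measurement_order()) == [2, 1]

    def test_boundary_centroid_goes_to_lower_cell(self):
        labels = np.zeros((200, 200), dtype=np.int32)
        labels[99:102, 99:102] = 1  # centroid exactly (100, 100)
        masks = assign_wells(ingest_masks(labels), (2, 2))
        assert masks.wells[1] == (0, 0)

    def test_overfull_well_flagged(self):
        labels = np.zeros((200, 200), dtype=np.int32)
        for i, r in enumerate((20, 80, 140), start=1):
            labels[r:r + 10, 50:60] = i
        masks = assign_wells(ingest_masks(labels), (1, 1))
        assert any("3 slices" in w for w in masks.warnings)

    def test_empty_maskset_passes_through(self):
        masks = assign_wells(ingest_masks(np.zeros((50, 50), dtype=np.int32)),
                             (2, 3))
        assert len(masks) == 0


class TestFallbackSegmentation:
    def test_recovers_synthetic_slices(self):
        spec = simulate.PlateSpec(seed=2)
        image, gt = simulate.generate_plate_image(spec)
        masks = segment_slices_fallback(image.brightfield)
        assert len(masks) == len(gt.slices)
        for lbl in gt.slices:
            gtm = gt.slice_mask(lbl)
            iou = max(((masks.mask(k) & gtm).sum() / (masks.mask(k) | gtm).sum())
                      for k in masks.labels)
            assert iou >= 0.9

    def test_robust_to_reflection_artifacts(self):
        spec = simulate.PlateSpec(seed=4, reflection_artifacts=True, noise_sd=1.0)
        image, gt = simulate.generate_plate_image(spec)
        masks = segment_slices_fallback(image.brightfield)
        assert len(masks) == len(gt.slices)

    def test_blank_image_yields_empty_maskset_with_warning(self):
        masks = segment_slices_fallback(np.zeros((100, 100)))
        assert len(masks) == 0
        assert masks.warnings

    def test_touching_slices_split_by_watershed(self):
        img = np.full((200, 360), 10.0)
        m1 = ellipse_mask((200, 360), (100, 110), (55, 30), 0.0)
        m2 = ellipse_mask((200, 360), (100, 222), (55, 30), 0.0)  # touching
        img[m1 | m2] = 80.0
        assert (m1 & m2).sum() < 20  # nearly tangent
        masks = segment_slices_fallback(img)
        assert len(masks) == 2
        for truth in (m1, m2):
            iou = max(((masks.mask(k) & truth).sum() / (masks.mask(k) | truth).sum())
                      for k in masks.labels)
            assert iou >= 0.8


@pytest.fixture(scope="module")
def plate():
    spots = (
        simulate.TumorSpot((0, 0), "top", "left", 10000.0),
        simulate.TumorSpot((0, 0), "top", "right", 500.0),
        simulate.TumorSpot((1, 2), "bottom", "right", 50000.0),
    )
    spec = simulate.PlateSpec(tumor_spots=spots, seed=3)
    return simulate.generate_plate_image(spec)


class TestMeasurement:

    def test_spot_recovered_within_five_percent(self, plate):
        image, gt = plate
        lbl = gt.label_for((0, 0), "top")
        hemi = gt.hemisphere_mask(lbl, "left")
        m = measure_tumor_signal(image, hemi)
        assert abs(m.value - 10000.0) / 10000.0 < 0.05

    def test_hundredfold_intensity_range_in_one_image(self, plate):
        image, gt = plate
        for well, pos, side, truth in (((0, 0), "top", "right", 500.0),
                                       ((1, 2), "bottom", "right", 50000.0)):
            hemi = gt.hemisphere_mask(gt.label_for(well, pos), side)
            m = measure_tumor_signal(image, hemi)
            assert abs(m.value - truth) / truth < 0.05

    def test_signal_free_hemisphere_measures_zero_background(self, plate):
        image, gt = plate
        hemi = gt.hemisphere_mask(gt.label_for((0, 1), "top"), "left")
        m = measure_tumor_signal(image, hemi)
        assert m.value == 0.0
        assert m.degenerate

    def test_pi_mean_constant_field(self):
        image = PlateImage(brightfield=np.zeros((20, 20)),
                           signal=np.full((20, 20), 40.0), channel_kind="PI")
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert measure_pi(image, mask).value == 40.0

    def test_pi_mean_from_synthetic_plate(self):
        image, gt = simulate.generate_plate_image(
            simulate.PlateSpec(pi_mean=120.0, seed=3))
        m = measure_pi(image, gt.slice_mask(1))
        assert m.value == pytest.approx(120.0, rel=0.01)

    def test_single_pixel_mask(self):
        sig = np.zeros((5, 5))
        sig[2, 2] = 7.0
        image = PlateImage(brightfield=np.zeros((5, 5)), signal=sig)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert measure_pi(image, mask).value == 7.0

    def test_empty_mask_rejected(self, plate):
        image, _ = plate
        with pytest.raises(ValueError):
            measure_pi(image, np.zeros(image.shape, dtype=bool))
        with pytest.raises(ValueError):
            measure_tumor_signal(image, np.zeros(image.shape, dtype=bool))


class TestD1T:
    def _single_spot_image(self, intensity, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        H = W = 200
        yy, xx = np.mgrid[0:H, 0:W]
        sigma = 4.0
        g = np.exp(-((yy - 100) ** 2 + (xx - 100) ** 2) / (2 * sigma**2))
        sig = intensity * g / g.sum()
        if noise_sd:
            sig = np.clip(sig + rng.normal(0, noise_sd, (H, W)), 0, None)
        return PlateImage(brightfield=np.zeros((H, W)), signal=sig,
                          channel_kind="mCherry")

    def test_spot_recovered_within_five_percent(self):
        m = measure_d1t(self._single_spot_image(2000.0))
        assert abs(m.value - 2000.0) / 2000.0 < 0.05

    def test_all_zero_image_flagged_zero(self):
        image = PlateImage(brightfield=np.zeros((50, 50)),
                           signal=np.zeros((50, 50)), channel_kind="mCherry")
        m = measure_d1t(image)
        assert m.value == 0.0
        assert m.degenerate

    def test_dim_spot_above_noise_detected(self):
        # peak amplitude ~2x the background SD
        sigma_noise = 1.0
        intensity = 2.0 * sigma_noise * 2 * math.pi * 16  # peak = 2*SD, sigma=4
        m = measure_d1t(self._single_spot_image(intensity, noise_sd=sigma_noise,
                                                seed=8))
        assert m.value > 0.0


def test_measure_plate_tumor_mode_orders_and_measures(tmp_path):
    spots = (simulate.TumorSpot((0, 0), "top", "left", 8000.0),)
    image, gt = simulate.generate_plate_image(
        simulate.PlateSpec(tumor_spots=spots, seed=6))
    masks = assign_wells(ingest_masks(gt.label_image), (2, 3))
    df = imaging.measure_plate(image, masks, mode="tumor")
    assert len(df) == 2 * len(gt.slices)  # two hemispheres per slice
    top_left = df.iloc[0]
    assert (top_left.well_row, top_left.well_col) == (0, 0)
    assert top_left.position == "top"
    assert df["value"].max() == pytest.approx(8000.0, rel=0.05)
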