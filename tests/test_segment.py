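"""Vegetation indices, HSV thresholding, Otsu, masks and ROI counting.

Each non-trivial operation is checked against an independent brute-force
oracle: hand arithmetic for the index formulas, per-pixel re-evaluation for
the HSV box, exhaustive 256-cut search for Otsu, and a ray-casting
point-in-polygon routine for ROI counts.
"""

import numpy as np
import pytest

from citrusyield.errors import (ColorSpaceError, DegenerateHistogramError,
                                InvalidParameterError)
from citrusyield.preprocess import RasterImage, rgb_to_hsv_255
from citrusyield.segment import (HSVRange, IndexMap, Mask, TreeROI,
                                 cive_index, count_pixels, fruit_mask,
                                 hsv_threshold, i1_index, ipca_index,
                                 threshold_index, tree_mask)


def _rgb(*pixels) -> RasterImage:
    arr = np.array(pixels, dtype=np.uint8).reshape(1, -1, 3)
    return RasterImage(arr, "RGB")


class TestIndices:
    def test_ipca_hand_values(self):
        img = _rgb((10, 10, 10), (200, 180, 40))
        vals = ipca_index(img).values[0]
        assert vals[0] == 0.0
        # 0.994*160 + 0.961*140 + 0.914*160
        assert vals[1] == pytest.approx(439.82)

    def test_ipca_verbatim_equals_algebraic_simplification(self, rng):
        px = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        img = RasterImage(px)
        r, g, b = px[..., 0].astype(float), px[..., 1].astype(float), px[..., 2].astype(float)
        simplified = (0.994 + 0.914) * np.abs(r - b) + 0.961 * np.abs(g - b)
        np.testing.assert_allclose(ipca_index(img).values, simplified, rtol=1e-12)

    def test_ipca_not_shift_invariant(self):
        # adding a constant to all channels preserves |.| arguments, but the
        # clamp at 255 and sign structure mean shift invariance holds only
        # pre-clamp; verify invariance where no argument changes sign
        a = _rgb((10, 40, 30))
        b = _rgb((110, 140, 130))
        assert ipca_index(a).values[0, 0] == pytest.approx(
            ipca_index(b).values[0, 0])

    def test_cive_hand_values(self):
        img = _rgb((0, 0, 0), (100, 100, 100))
        vals = cive_index(img).values[0]
        assert vals[0] == pytest.approx(18.78)
        assert vals[1] == pytest.approx(20.28)

    def test_cive_decreasing_in_green(self):
        img = _rgb((100, 50, 100), (100, 200, 100))
        vals = cive_index(img).values[0]
        assert vals[1] < vals[0]

    def test_i1_hand_values(self):
        img = _rgb((7, 7, 7), (100, 50, 30))
        vals = i1_index(img).values[0]
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(90.0)

    def test_indices_reject_hsv_input(self):
        hsv = RasterImage(np.zeros((2, 2, 3), np.uint8), "HSV")
        for fn in (ipca_index, cive_index, i1_index):
            with pytest.raises(ColorSpaceError):
                fn(hsv)


class TestHSVThreshold:
    def test_default_range_membership(self):
        img = RasterImage(
            np.array([[29, 137, 240], [29, 137, 200]], np.uint8).reshape(1, 2, 3),
            "HSV")
        mask = hsv_threshold(img)
        assert mask.values[0, 0]        # mid-range of every channel
        assert not mask.values[0, 1]    # V below 221

    def test_matches_per_pixel_brute_force(self, rng):
        px = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        img = RasterImage(px, "HSV")
        rng_box = HSVRange()
        mask = hsv_threshold(img, rng_box)
        lows, highs = rng_box.lows, rng_box.highs
        expected = np.zeros((32, 32), bool)
        for i in range(32):
            for j in range(32):
                expected[i, j] = all(
                    lows[c] <= px[i, j, c] <= highs[c] for c in range(3))
        np.testing.assert_array_equal(mask.values, expected)

    def test_rejects_rgb_input(self):
        with pytest.raises(ColorSpaceError):
            hsv_threshold(RasterImage(np.zeros((2, 2, 3), np.uint8), "RGB"))

    def test_wraparound_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            HSVRange(h_lo=240, h_hi=10)


def _binned_between_class_variance(values: np.ndarray, cut: float) -> float:
    """Between-class variance of the 256-bin index histogram at a cut.

    Classes are formed from histogram bins (the objective Otsu optimizes),
    with class means taken over bin centers."""
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    lo = centers <= cut
    w0, w1 = hist[lo].sum(), hist[~lo].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (hist[lo] * centers[lo]).sum() / w0
    mu1 = (hist[~lo] * centers[~lo]).sum() / w1
    n = hist.sum()
    return (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2


def _otsu_oracle_max(values: np.ndarray) -> float:
    """Best achievable binned between-class variance over all 256 candidate
    cuts, by exhaustive search; independent of skimage."""
    _, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return max(_binned_between_class_variance(values, c) for c in centers)


class TestThresholdIndex:
    def test_otsu_cut_between_two_delta_peaks(self):
        vals = np.array([10.0] * 40 + [200.0] * 24).reshape(8, 8)
        mask = threshold_index(IndexMap(vals, "I_1"), "otsu", polarity="above")
        assert mask.values.sum() == 24  # exactly the high peak

    def test_otsu_achieves_exhaustive_search_optimum(self, rng):
        # the chosen cut must realize the best between-class variance found
        # by brute force over all 256 candidate cuts (the cut *position*
        # within an empty-bin plateau is arbitrary, the partition is not)
        for _ in range(10):
            vals = rng.normal(50, 20, (8, 8)) + \
                (rng.random((8, 8)) > 0.5) * rng.normal(120, 10)
            from skimage.filters import threshold_otsu
            cut = threshold_otsu(vals.ravel(), nbins=256)
            mask = threshold_index(IndexMap(vals, "I_1"), "otsu",
                                   polarity="above")
            np.testing.assert_array_equal(mask.values, vals > cut)
            achieved = _binned_between_class_variance(vals, cut)
            assert achieved == pytest.approx(_otsu_oracle_max(vals), rel=1e-9)

    def test_otsu_mask_exact_on_separated_clusters(self, rng):
        # with a guaranteed gap every cut in the gap induces the same mask
        low = rng.uniform(0, 40, 50)
        high = rng.uniform(180, 220, 14)
        vals = rng.permutation(np.concatenate([low, high])).reshape(8, 8)
        mask = threshold_index(IndexMap(vals, "I_1"), "otsu", polarity="above")
        np.testing.assert_array_equal(mask.values, vals >= 180)

    def test_fixed_strategy_is_ge_cut(self, rng):
        vals = rng.normal(0, 1, (10, 10))
        mask = threshold_index(IndexMap(vals, "CIVE"), "fixed",
                               fixed_value=0.3, polarity="above")
        np.testing.assert_array_equal(mask.values, vals >= 0.3)
        below = threshold_index(IndexMap(vals, "CIVE"), "fixed",
                                fixed_value=0.3, polarity="below")
        np.testing.assert_array_equal(below.values, ~mask.values)

    def test_constant_map_raises_helpful_error(self):
        with pytest.raises(DegenerateHistogramError, match="fixed"):
            threshold_index(IndexMap(np.full((4, 4), 2.0), "I_1"), "otsu")


class TestFruitMask:
    def test_empty_when_nothing_in_hsv_range(self):
        img = _rgb((0, 80, 0), (90, 60, 30), (128, 128, 128))
        mask = fruit_mask(img, "hsv", tree=Mask(np.ones((1, 3), bool)))
        assert mask.count() == 0

    def test_intersection_excludes_fruit_outside_tree(self):
        # two fruit-colored pixels; the tree mask covers only the first
        img = _rgb((245, 185, 95), (245, 185, 95))
        tree = Mask(np.array([[True, False]]))
        mask = fruit_mask(img, "hsv", tree=tree)
        assert mask.values.tolist() == [[True, False]]

    def test_result_subset_of_tree_mask(self, rng):
        px = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
        img = RasterImage(px)
        tree = Mask(rng.random((24, 24)) > 0.5)
        for method in ("hsv", "ipca", "cive", "i1"):
            m = fruit_mask(img, method, tree=tree)
            assert not np.any(m.values & ~tree.values)
            assert m.provenance == "intersection"

    def test_counts_recomputed_after_remapping(self):
        # a monotone channel remap must change the mask, proving no caching
        from citrusyield.preprocess import equalize_histogram
        rng = np.random.default_rng(5)
        px = np.clip(rng.normal(150, 30, (32, 32, 3)), 0, 255).astype(np.uint8)
        px[4:8, 4:8] = (200, 150, 70)  # dim orange patch
        img = RasterImage(px)
        tree = Mask(np.ones((32, 32), bool))
        before = fruit_mask(img, "hsv", tree=tree).count()
        after = fruit_mask(equalize_histogram(img), "hsv", tree=tree).count()
        assert before != after


def _point_in_polygon_oracle(poly: np.ndarray, x: float, y: float) -> bool:
    """Ray casting with an on-edge check, independent of shapely."""
    n = len(poly)
    # boundary: distance to any segment below tolerance
    for i in range(n):
        (x1, y1), (x2, y2) = poly[i], poly[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        t = 0.0 if dx == dy == 0 else np.clip(
            ((x - x1) * dx + (y - y1) * dy) / (dx * dx + dy * dy), 0, 1)
        if (x1 + t * dx - x) ** 2 + (y1 + t * dy - y) ** 2 < 1e-18:
            return True
    inside = False
    for i in range(n):
        (x1, y1), (x2, y2) = poly[i], poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xi:
                inside = not inside
    return inside


class TestCountPixels:
    def test_full_mask_rectangular_roi(self):
        mask = Mask(np.ones((20, 30), bool))
        roi = TreeROI("t", [(2, 3), (11, 3), (11, 8), (2, 8)])
        # 10 x 6 grid of pixel centers, boundary included
        assert count_pixels(mask, roi) == 60

    def test_empty_mask_counts_zero(self):
        mask = Mask(np.zeros((20, 20), bool))
        roi = TreeROI("t", [(0, 0), (19, 0), (9, 19)])
        assert count_pixels(mask, roi) == 0

    def test_agrees_with_ray_casting_oracle(self, rng):
        mask = Mask(rng.random((40, 40)) > 0.4)
        poly = np.array([(3.2, 5.1), (33.7, 2.4), (37.1, 21.6),
                         (20.3, 36.8), (5.6, 28.9)])
        roi = TreeROI("t", poly)
        got = count_pixels(mask, roi)
        expected = sum(
            _point_in_polygon_oracle(poly, float(x), float(y))
            for y, x in zip(*np.nonzero(mask.values)))
        assert got == expected

    def test_roi_outside_image_warns_and_counts_zero(self):
        mask = Mask(np.ones((10, 10), bool))
        roi = TreeROI("far", [(100, 100), (110, 100), (105, 110)])
        with pytest.warns(UserWarning, match="outside"):
            assert count_pixels(mask, roi) == 0

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(InvalidParameterError, match="self-intersect"):
            TreeROI("bow", [(0, 0), (10, 10), (10, 0), (0, 10)])


class TestTreeMask:
    def test_high_index_is_foreground(self):
        # bright orange fruit on gray ground: fruit has the high index
        px = np.tile(np.array([150, 140, 125], np.uint8), (16, 16, 1))
        px[4:8, 4:8] = (245, 185, 95)
        m = tree_mask(RasterImage(px))
        assert m.values[5, 5]
        assert not m.values[0, 0]
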