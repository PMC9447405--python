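import numpy as np
import pytest

from spotquant import (
    GridSpec,
    Histogram,
    binarize_global,
    binarize_local,
    make_grid,
    otsu_threshold,
    threshold_suite,
)

from conftest import make_grey


def hist_of(values, bit_depth=8):
    return Histogram.from_pixels(np.asarray(values), bit_depth)


def brute_force_otsu(h):
    """Independent exhaustive argmax of the between-class variance."""
    c = h.counts.astype(float)
    v = np.arange(256.0)
    best, best_val = None, -1.0
    for t in range(255):
        w0, w1 = c[: t + 1].sum(), c[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (c[: t + 1] @ v[: t + 1]) / w0
        m1 = (c[t + 1 :] @ v[t + 1 :]) / w1
        val = w0 * w1 * (m0 - m1) ** 2
        if val > best_val:
            best_val, best = val, t
    return best


def random_histogram(seed):
    """A mixture of 1-3 clipped Gaussian bin clusters."""
    rng = np.random.default_rng(seed)
    parts = [
        np.clip(rng.normal(rng.uniform(10, 240), rng.uniform(2, 30), rng.integers(20, 400)), 0, 255)
        for _ in range(rng.integers(1, 4))
    ]
    return hist_of(np.concatenate(parts).astype(np.uint8))


class TestOtsu:
    def test_constant_histogram_is_degenerate(self):
        assert otsu_threshold(hist_of([7] * 10)) is None

    def test_bimodal_tie_broken_smallest(self):
        # any split in [50, 199] attains the maximal between-class variance
        assert otsu_threshold(hist_of([50] * 100 + [200] * 100)) == 50

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        h = random_histogram(seed)
        assert otsu_threshold(h) == brute_force_otsu(h)

    def test_invariant_to_count_scaling(self):
        h = random_histogram(999)
        scaled = Histogram(counts=h.counts * 17, bin_width=h.bin_width)
        assert otsu_threshold(h) == otsu_threshold(scaled)


class TestSuite:
    def test_mean_method_floors_pixel_mean(self):
        assert threshold_suite(hist_of([0, 0, 100, 100]), "mean") == 50

    def test_otsu_dispatch_identity(self):
        h = random_histogram(3)
        assert threshold_suite(h, "otsu") == otsu_threshold(h)

    def test_isodata_converges_to_midpoint(self):
        assert threshold_suite(hist_of([50] * 100 + [200] * 100), "isodata") == 125

    def test_unknown_method_lists_available(self):
        with pytest.raises(ValueError, match="otsu"):
            threshold_suite(hist_of([1, 2]), "nope")

    @pytest.mark.parametrize("method", ["mean", "isodata", "triangle", "li", "yen"])
    def test_degenerate_histogram_returns_none(self, method):
        assert threshold_suite(hist_of([9] * 20), method) is None

    @pytest.mark.parametrize("method", ["otsu", "isodata", "triangle", "li", "yen", "mean"])
    def test_agrees_with_skimage_reference(self, method):
        filters = pytest.importorskip("skimage.filters")
        sk = getattr(filters, f"threshold_{method}")
        rng = np.random.default_rng(7)
        for _ in range(10):
            px = np.clip(
                rng.normal(60, 15, (60, 60))
                + (rng.random((60, 60)) < 0.2) * rng.uniform(50, 150),
                0,
                255,
            ).astype(np.uint8)
            ours = threshold_suite(hist_of(px), method)
            assert abs(ours - float(sk(px))) <= 2

    def test_16bit_histogram_uses_256_wide_bins(self):
        px = np.array([0] * 50 + [60000] * 50, dtype=np.uint16)
        h = hist_of(px, bit_depth=16)
        assert h.bin_width == 256
        t = threshold_suite(h, "otsu")
        # threshold in native units separates the two clusters
        assert 0 < h.bin_to_intensity(t) < 60000


def two_spot_image():
    px = np.full((40, 80), 20, dtype=np.uint8)
    px[10:30, 10:30] = 200
    px[10:30, 50:70] = 180
    return make_grey(px)


class TestBinarizeGlobal:
    def test_bright_spots_on_dark_background_all_found(self):
        mask = binarize_global(two_spot_image())
        assert mask.pixels[15, 15] and mask.pixels[15, 60]
        assert not mask.pixels[0, 0]
        assert mask.foreground_area == 2 * 400

    def test_constant_image_all_background(self):
        mask = binarize_global(make_grey(np.full((10, 10), 5)))
        assert mask.foreground_area == 0
        assert "degenerate" in mask.flags

    def test_gradient_background_loses_faint_spots(self, gradient_demo):
        img, truth = gradient_demo
        mask = binarize_global(img)
        cells = make_grid(img, GridSpec(7, 10))
        empty = sum(
            1 for c in cells if c.extract(mask.pixels).sum() < 4
        )
        assert empty >= 1  # the global-threshold failure mode

    def test_foreground_monotone_in_threshold(self):
        img = two_spot_image()
        areas = [(img.pixels > t).sum() for t in range(0, 256, 16)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestBinarizeLocal:
    def test_retains_all_spots_on_gradient_background(self, gradient_demo):
        img, truth = gradient_demo
        cells = make_grid(img, GridSpec(7, 10))
        masks = binarize_local(img, cells)
        assert sum(not cm.is_empty for cm in masks) == 70

    def test_uniform_cell_flagged_empty(self):
        img = make_grey(np.full((20, 20), 33))
        cells = make_grid(img, GridSpec(1, 1))
        (cm,) = binarize_local(img, cells)
        assert cm.is_empty and cm.mask.foreground_area == 0

    def test_noise_only_cell_flagged_empty(self):
        # a zero-amplitude (negative control) cell must not yield a spot
        rng = np.random.default_rng(11)
        px = np.clip(rng.normal(30, 3, (40, 40)), 0, 255).astype(np.uint8)
        (cm,) = binarize_local(make_grey(px), make_grid(make_grey(px), GridSpec(1, 1)))
        assert cm.is_empty

    def test_one_by_one_grid_matches_global(self):
        img = two_spot_image()
        cells = make_grid(img, GridSpec(1, 1))
        (cm,) = binarize_local(img, cells)
        global_mask = binarize_global(img)
        np.testing.assert_array_equal(cm.mask.pixels, global_mask.pixels)
        assert cm.mask.threshold_used == global_mask.threshold_used
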