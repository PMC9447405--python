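import numpy as np
import pytest

from spotquant import (
    Background,
    GridSpec,
    RasterImage,
    SyntheticSpec,
    estimate_background,
    measure_spot,
    measurements_to_frame,
    quantify_array,
    render_array,
)
from spotquant.synthetic import ArrayLayout, LayoutEntry, amplitudes_from_layout, default_antigen_layout
from spotquant.thresholding import BinaryMask

from conftest import make_grey


def mask_of(bools):
    return BinaryMask(pixels=np.asarray(bools, dtype=bool), threshold_used=None, method="test")


class TestEstimateBackground:
    def test_uniform_background(self):
        px = np.full((10, 10), 20)
        px[3:7, 3:7] = 200
        bg = estimate_background(px, mask_of(px > 100))
        assert bg == 20

    def test_ramp_background_median(self):
        px = np.tile(np.arange(10, 31), (5, 1))  # values 10..30 per row
        bg = estimate_background(px, mask_of(np.zeros_like(px)))
        assert bg == 20

    def test_all_foreground_falls_back_to_minimum(self, caplog):
        px = np.array([[5, 9], [7, 8]])
        with caplog.at_level("WARNING", logger="spotquant.quantify"):
            bg = estimate_background(px, mask_of(np.ones_like(px)))
        assert bg == 5
        assert any("all-foreground" in r.message for r in caplog.records)


class TestMeasureSpot:
    def test_uniform_spot_minus_uniform_background(self):
        px = np.full((10, 10), 20)
        px[3:7, 3:7] = 200
        m = measure_spot(px, mask_of(px > 100), bg=20.0)
        assert m.net_intensity == 180
        assert m.fg_area == 16
        assert m.fg_sum == 16 * 180
        assert m.flags == frozenset()

    def test_empty_cell_all_zero_with_flag(self):
        px = np.full((10, 10), 20)
        m = measure_spot(px, mask_of(np.zeros_like(px)), bg=20.0)
        assert m.net_intensity == 0 and m.fg_area == 0 and m.fg_mean == 0
        assert "empty" in m.flags

    def test_saturated_flag(self):
        px = np.full((10, 10), 10)
        px[2:8, 2:8] = 255
        m = measure_spot(px, mask_of(px > 100), bg=10.0, max_value=255)
        assert "saturated" in m.flags

    def test_edge_clipped_flag(self):
        px = np.full((10, 10), 10)
        px[0:4, 0:4] = 200  # touches the top-left border
        m = measure_spot(px, mask_of(px > 100), bg=10.0)
        assert "edge_clipped" in m.flags

    def test_net_clipped_at_zero(self):
        px = np.full((5, 5), 10)
        px[2, 2] = 30
        m = measure_spot(px, mask_of(px > 20), bg=50.0)
        assert m.net_intensity == 0 and m.fg_sum == 0

    def test_irregular_spot_amplitude_recovered_on_ramp(self):
        # arbitrary-shaped spots are handled: amplitude 100 within +-10%
        layout = ArrayLayout(
            n_rows=1, n_cols=1,
            entries=(LayoutEntry(row=0, col=0, analyte="x", concentration=1.0),),
        )
        spec = SyntheticSpec(
            layout=layout,
            amplitude_map=np.array([[100.0]]),
            shape="irregular-blob",
            background=Background(kind="linear-gradient", base=10.0, amplitude=20.0),
            noise_sigma=1.0,
            seed=5,
        )
        img, truth = render_array(spec)
        (m,) = quantify_array(img, GridSpec(1, 1))
        assert m.net_intensity == pytest.approx(100.0, rel=0.10)


class TestQuantifyArray:
    def test_seventy_spot_array(self, gradient_demo_measurements):
        measurements, truth = gradient_demo_measurements
        assert len(measurements) == 70
        assert [(m.row, m.col) for m in measurements] == [
            (r, c) for r in range(1, 8) for c in range(1, 11)
        ]

    def test_one_by_one_grid_is_measure_spot_on_whole_image(self):
        px = np.full((40, 40), 15, dtype=np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        px[(yy - 20) ** 2 + (xx - 20) ** 2 <= 81] = 140
        img = RasterImage(pixels=px, bit_depth=8)
        (m,) = quantify_array(img, GridSpec(1, 1))
        assert m.net_intensity == pytest.approx(125.0, abs=1.0)

    def test_deterministic_output(self, gradient_demo):
        img, _ = gradient_demo
        a = measurements_to_frame(quantify_array(img, GridSpec(7, 10)))
        b = measurements_to_frame(quantify_array(img, GridSpec(7, 10)))
        assert a.to_csv() == b.to_csv()

    def test_invalid_mode_rejected(self, gradient_demo):
        img, _ = gradient_demo
        with pytest.raises(ValueError, match="mode"):
            quantify_array(img, GridSpec(7, 10), mode="hybrid")

    def test_offset_invariance(self):
        """Adding a constant (without saturation) leaves net intensities put."""
        layout = default_antigen_layout()
        spec = SyntheticSpec(
            layout=layout,
            amplitude_map=amplitudes_from_layout(layout, top_amplitude=150.0),
            background=Background(kind="uniform", base=30.0),
            noise_sigma=2.0,
            seed=5,
        )
        img, _ = render_array(spec)
        assert img.pixels.max() <= 230  # headroom for the shift
        shifted = RasterImage(
            pixels=(img.pixels.astype(np.int16) + 25).astype(np.uint8), bit_depth=8
        )
        before = quantify_array(img, GridSpec(7, 5))
        after = quantify_array(shifted, GridSpec(7, 5))
        deltas = [abs(a.net_intensity - b.net_intensity) for a, b in zip(before, after)]
        assert max(deltas) <= 1.0

    def test_local_beats_global_on_gradient_background(self, gradient_demo):
        """Local-mode quantification has smaller error against ground truth."""
        img, truth = gradient_demo
        amp = truth.amplitudes

        def mae(mode):
            ms = quantify_array(img, GridSpec(7, 10), mode=mode)
            net = np.array([m.net_intensity for m in ms])
            return np.abs(net - amp).mean()

        assert mae("local") < mae("global")

    def test_dose_response_monotone(self):
        from spotquant import render_antigen_array

        img, truth = render_antigen_array(seed=3)
        ms = quantify_array(img, GridSpec(7, 5))
        net = {(m.row, m.col): m.net_intensity for m in ms}
        frame = truth.to_frame()
        for analyte, sub in frame[frame.analyte != "PBS"].groupby("analyte"):
            ordered = sub.sort_values("concentration")
            values = [net[(r.row, r.col)] for r in ordered.itertuples()]
            assert all(a < b for a, b in zip(values, values[1:])), analyte
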