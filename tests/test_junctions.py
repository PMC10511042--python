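"""PA spot morphometrics and TJ network length."""
import math

import numpy as np
import pytest

from spheromet import junctions as J
from spheromet.synthetic import generate_junction_image
from spheromet.synthetic.junctions import draw_segment


def brute_force_feret(pixels: np.ndarray) -> float:
    """Oracle: exhaustive max distance over all pixel-corner pairs."""
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (np.atleast_2d(pixels)[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return float(d.max())


class TestProjectMax:
    def test_single_slice_is_identity(self):
        img = np.random.default_rng(0).random((1, 30, 30))
        assert np.array_equal(J.project_max(img), img[0])

    def test_disjoint_spots_both_survive(self):
        stack = np.zeros((2, 20, 20))
        stack[0, 5, 5] = 1.0
        stack[1, 15, 15] = 2.0
        proj = J.project_max(stack)
        assert proj[5, 5] == 1.0 and proj[15, 15] == 2.0

    def test_global_max_preserved_per_pixel(self):
        rng = np.random.default_rng(1)
        stack = rng.random((6, 16, 16))
        proj = J.project_max(stack)
        assert np.array_equal(proj, stack.max(axis=0))


class TestMaxFeret:
    def test_single_pixel_is_sqrt_two(self):
        assert J.max_feret(np.array([[3, 7]])) == pytest.approx(math.sqrt(2))

    def test_horizontal_bar(self):
        bar = np.array([[0, i] for i in range(10)])
        assert J.max_feret(bar) == pytest.approx(math.hypot(10, 1))

    def test_lower_bound_by_bounding_box(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pix = rng.integers(0, 20, size=(rng.integers(1, 30), 2))
            bb = pix.max(axis=0) - pix.min(axis=0) + 1
            assert J.max_feret(pix) >= max(bb) - 1e-9

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            pix = np.unique(rng.integers(0, 25, size=(n, 2)), axis=0)
            assert J.max_feret(pix) == pytest.approx(brute_force_feret(pix), abs=1e-9)


class TestDetectPA:
    def test_programmed_spots_recovered_with_feret_tolerance(self):
        chans, truth = generate_junction_image(16, pa_spec=(12, 10.0), seed=9)
        pas = J.detect_pa(chans["pa"], chans["actin"])
        assert len(pas) == 12
        for p in pas:
            assert abs(p.max_feret - 10.0) <= 1.5
            assert p.attached_to_actin

    def test_detached_spot_rejected(self):
        spot = np.zeros((60, 60), np.float32)
        actin = np.zeros((60, 60), np.float32)
        draw_segment(spot, (10.0, 10.0), (10.0, 18.0), 1.0)   # far from actin
        draw_segment(actin, (45.0, 5.0), (45.0, 55.0), 2.0)
        pas = J.detect_pa(spot, actin, spot_threshold=0.5, actin_threshold=0.5)
        assert pas == []
        kept = J.detect_pa(spot, actin, spot_threshold=0.5, actin_threshold=0.5,
                           keep_detached=True)
        assert len(kept) == 1 and not kept[0].attached_to_actin

    def test_empty_spot_channel_gives_empty_list(self):
        blank = np.zeros((40, 40), np.float32)
        actin = np.zeros((40, 40), np.float32)
        draw_segment(actin, (20.0, 0.0), (20.0, 39.0), 2.0)
        assert J.detect_pa(blank, actin, spot_threshold=0.5, actin_threshold=0.5) == []

    def test_unregistered_shapes_rejected(self):
        with pytest.raises(ValueError, match="registered"):
            J.detect_pa(np.zeros((10, 10)), np.zeros((12, 10)))


class TestPADensity:
    def test_zero_objects(self):
        assert J.pa_density([], 100.0) == 0.0

    def test_arithmetic(self):
        objs = [object()] * 10
        assert J.pa_density(objs, 100 * 100) == pytest.approx(1e-3)

    def test_programmed_count_over_area(self):
        chans, truth = generate_junction_image(16, pa_spec=(10, 9.0), seed=10)
        pas = J.detect_pa(chans["pa"], chans["actin"])
        area = float(chans["pa"].size)
        assert J.pa_density(pas, area) == pytest.approx(10 / area)


class TestTJLength:
    def test_straight_single_pixel_line_counts_exactly(self):
        img = np.zeros((50, 80), np.float32)
        img[25, 10:70] = 1.0
        meas = J.tj_length(img, cell_count=2, tophat_radius=4)
        assert meas.total_length_px == pytest.approx(60, abs=2)
        assert meas.per_cell == meas.total_length_px / 2

    def test_hexagonal_network_recovered_within_five_percent(self):
        chans, truth = generate_junction_image(2, pa_spec=(0, 10.0), seed=11,
                                               shape=(400, 400),
                                               layout="hexagonal", hex_side=40.0)
        meas = J.tj_length(chans["tj"], chans["nuclei"])
        err = abs(meas.traced_length_px - truth.true_tj_length) / truth.true_tj_length
        assert err < 0.05
        assert meas.cell_count == truth.true_cell_count

    def test_round_spots_suppressed_by_linear_enhancement(self):
        img = np.zeros((100, 100), np.float32)
        yy, xx = np.mgrid[0:100, 0:100]
        for cy, cx in [(25, 25), (70, 60)]:
            img += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 8.0 ** 2)))
        meas = J.tj_length(img, cell_count=1, tophat_radius=4)
        assert meas.total_length_px < 40  # essentially no line structure left

    def test_skeleton_length_invariant_under_thickening(self):
        base_truth = None
        lengths = []
        for halfwidth in (1.0, 2.0, 3.0):
            chans, truth = generate_junction_image(
                2, pa_spec=(0, 10.0), seed=12, shape=(300, 300),
                layout="hexagonal", hex_side=45.0, tj_halfwidth=halfwidth,
                noise_sigma=0.0)
            meas = J.tj_length(chans["tj"], cell_count=truth.true_cell_count,
                               tophat_radius=int(2 * halfwidth) + 2)
            lengths.append(meas.traced_length_px)
            base_truth = truth.true_tj_length
        for ln in lengths:
            assert abs(ln - base_truth) / base_truth < 0.05

    def test_zero_nuclei_flags_per_cell(self):
        img = np.zeros((50, 50), np.float32)
        img[25, 5:45] = 1.0
        meas = J.tj_length(img, cell_count=0)
        with pytest.raises(ZeroDivisionError):
            _ = meas.per_cell

    def test_per_cell_identity(self):
        chans, truth = generate_junction_image(12, pa_spec=(0, 10.0), seed=13)
        meas = J.tj_length(chans["tj"], chans["nuclei"])
        assert meas.per_cell * meas.cell_count == pytest.approx(meas.total_length_px)
        assert meas.per_area * meas.field_area == pytest.approx(meas.total_length_px)
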