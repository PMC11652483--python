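"""Binarization, threshold calibration, edge extraction, offset model."""

import numpy as np
import pytest

from epidlog.aperture import (
    ApertureError,
    BinaryAperture,
    LeafAperture,
    LeafPair,
    OffsetModel,
    apply_offset_correction,
    binarize,
    calibrate_threshold,
    cross_plane_count,
    extract_leaf_edges,
    measure_center_offsets,
)
from epidlog.config import DetectorGeometry
from epidlog.deconvolution import STAGE_DECONVOLVED, STAGE_IDEAL, FluenceImage
from epidlog.synthetic import (
    gen_offset_acquisition,
    ideal_box,
    make_sinusoidal_shift_fn,
    rasterize_aperture,
)


def _img(values, stage=STAGE_DECONVOLVED):
    return FluenceImage(values=np.asarray(values, dtype=float), stage=stage)


GEO = DetectorGeometry(resolution=256, pixel_mm=0.5)
# calibration boxes up to 20 cm need a wider field of view
BOX_GEO = DetectorGeometry(resolution=448, pixel_mm=0.5)


class TestBinarize:
    def test_uniform_above_threshold(self):
        ap = binarize(_img(np.full((32, 32), 30000.0)), 20000.0)
        assert ap.mask.all()
        assert ap.threshold_used == 20000.0

    def test_threshold_above_max_warns_empty(self):
        with pytest.warns(UserWarning, match="empty aperture"):
            ap = binarize(_img(np.full((32, 32), 100.0)), 200.0)
        assert not ap.mask.any()

    @pytest.mark.parametrize("t1,t2", [(100.0, 200.0), (5000.0, 20000.0)])
    def test_monotone_nesting(self, t1, t2):
        rng = np.random.default_rng(5)
        img = _img(rng.uniform(0, 30000, (64, 64)))
        lo = binarize(img, t1).mask
        hi = binarize(img, t2).mask
        assert np.all(hi <= lo)

    def test_wrong_stage_rejected(self):
        with pytest.raises(ApertureError, match="deconvolved"):
            binarize(_img(np.ones((8, 8)), stage=STAGE_IDEAL), 0.5)


class TestCalibrateThreshold:
    def test_ideal_boxes_valid_over_entire_grid(self):
        boxes = {s: _img(ideal_box(s, BOX_GEO) * 40000.0) for s in (5.0, 10.0, 15.0, 20.0)}
        cal = calibrate_threshold(boxes)
        # on ideal boxes every candidate in the 40-60% window is valid,
        # so the chosen midpoint is 50% of max: 20000
        assert cal.valid_range == (16000.0, 24000.0)
        assert cal.chosen == pytest.approx(20000.0)
        for ratios in cal.linearity_table.values():
            assert ratios == pytest.approx([2.0, 3.0, 4.0])

    def test_blur_deconvolve_keeps_exact_ratios(self, box_calibration_512):
        cal = box_calibration_512["calibration"]
        lo, hi = cal.valid_range
        assert lo <= cal.chosen <= hi
        masks = {
            s: box_calibration_512["deconvolved"][s].values >= cal.chosen
            for s in (5.0, 10.0, 15.0, 20.0)
        }
        c5 = cross_plane_count(masks[5.0])
        assert cross_plane_count(masks[10.0]) / c5 == pytest.approx(2.0)
        assert cross_plane_count(masks[15.0]) / c5 == pytest.approx(3.0)
        assert cross_plane_count(masks[20.0]) / c5 == pytest.approx(4.0, abs=0.02)

    def test_degenerate_sizes_rejected(self):
        boxes = {s: _img(ideal_box(s, BOX_GEO) * 40000.0) for s in (5.0, 10.0, 15.0)}
        with pytest.raises(ApertureError, match="4 distinct box sizes"):
            calibrate_threshold(boxes)

    def test_no_linear_threshold_reports_best(self):
        # wildly inconsistent "boxes": a constant image cannot satisfy ratios
        boxes = {
            5.0: _img(ideal_box(5.0, BOX_GEO) * 40000.0),
            10.0: _img(ideal_box(5.0, BOX_GEO) * 40000.0),
            15.0: _img(ideal_box(5.0, BOX_GEO) * 40000.0),
            20.0: _img(ideal_box(20.0, BOX_GEO) * 40000.0),
        }
        with pytest.raises(ApertureError, match="best candidate"):
            calibrate_threshold(boxes)


class TestExtractLeafEdges:
    def test_centered_box_geometry(self):
        geo = DetectorGeometry(resolution=512, pixel_mm=0.5)
        mask = ideal_box(5.0, geo) > 0
        ap = extract_leaf_edges(BinaryAperture(mask, 1.0), geo, [5.0] * 40)
        open_pairs = [p for p in ap.pairs if p.open]
        assert open_pairs
        for p in open_pairs:
            assert p.left_edge_mm == pytest.approx(-25.0)
            assert p.right_edge_mm == pytest.approx(25.0)

    def test_fully_closed_mask(self):
        ap = extract_leaf_edges(
            BinaryAperture(np.zeros((256, 256), bool), 1.0), GEO, [5.0] * 8
        )
        assert all(not p.open for p in ap.pairs)
        for p in ap.pairs:
            assert p.right_edge_mm - p.left_edge_mm == pytest.approx(0.5)

    def test_island_artifact_warns_and_keeps_longest(self):
        mask = np.zeros((256, 256), bool)
        mask[124:132, 60:70] = True  # short run
        mask[124:132, 100:140] = True  # long run
        with pytest.warns(UserWarning, match="island"):
            ap = extract_leaf_edges(BinaryAperture(mask, 1.0), GEO, [4.0])
        p = ap.pairs[0]
        assert p.left_edge_mm == pytest.approx(GEO.boundary_to_mm(100))
        assert p.right_edge_mm == pytest.approx(GEO.boundary_to_mm(140))

    def test_rasterize_extract_roundtrip_exact(self):
        # snapped random staircase aperture recovers exactly (offsets off)
        rng = np.random.default_rng(11)
        n_pairs = 12
        widths = [5.0] * n_pairs
        left = np.round(rng.uniform(-40, -5, n_pairs) / GEO.pixel_mm) * GEO.pixel_mm
        right = np.round(rng.uniform(5, 40, n_pairs) / GEO.pixel_mm) * GEO.pixel_mm
        mask = rasterize_aperture(left, right, widths, GEO) > 0
        ap = extract_leaf_edges(BinaryAperture(mask, 1.0), GEO, widths)
        got_l = np.array([p.left_edge_mm for p in ap.pairs])
        got_r = np.array([p.right_edge_mm for p in ap.pairs])
        assert got_l == pytest.approx(left, abs=1e-9)
        assert got_r == pytest.approx(right, abs=1e-9)


class TestOffsets:
    def test_identical_images_give_zero_offsets(self):
        images = gen_offset_acquisition(geometry=GEO)
        model = measure_center_offsets(images)
        assert all(v == 0 for v in model.sag_cross_left + model.sag_cross_right)
        assert all(v == 0 for row in model.coll_shift_cross for v in row)

    def test_injected_shift_at_single_pose_recovered(self):
        images = gen_offset_acquisition(
            shift_fn=lambda g, c: (3, 0) if g == 180.0 else (0, 0), geometry=GEO
        )
        model = measure_center_offsets(images)
        i180 = model.sag_gantry.index(180.0)
        assert model.sag_cross_left[i180] == pytest.approx(3.0)
        assert model.sag_cross_right[i180] == pytest.approx(3.0)
        assert sum(abs(v) for j, v in enumerate(model.sag_cross_left) if j != i180) == 0

    def test_sinusoidal_model_recovered_at_grid_poses(self):
        fn = make_sinusoidal_shift_fn(amp_cross_px=3.0, amp_in_px=2.0, coll_gain_px=4.0)
        model = measure_center_offsets(gen_offset_acquisition(shift_fn=fn, geometry=GEO))
        assert max(abs(v) for v in model.sag_cross_left) == pytest.approx(3.0, abs=0.5)
        for g in range(0, 360, 30):
            for c in range(-90, 91, 30):
                dx, dy = fn(float(g), float(c))
                left, right = model.cross_offsets_px(g, c)
                assert left == pytest.approx(dx, abs=0.5)
                assert right == pytest.approx(dx, abs=0.5)
                assert model.inplane_offset_px(g, c) == pytest.approx(dy, abs=0.5)

    def test_missing_pose_named(self):
        images = gen_offset_acquisition(geometry=GEO)
        del images[(180.0, 0.0)]
        with pytest.raises(ApertureError, match="gantry=180"):
            measure_center_offsets(images)

    def test_correction_cancels_injection(self):
        fn = make_sinusoidal_shift_fn(amp_cross_px=3.0, amp_in_px=0.0)
        model = measure_center_offsets(gen_offset_acquisition(shift_fn=fn, geometry=GEO))
        widths = [5.0] * 8
        left = np.full(8, -20.0)
        right = np.full(8, 20.0)
        for gantry in (90.0, 180.0, 270.0):
            dx, _ = fn(gantry, 0.0)
            mask = rasterize_aperture(left + dx * GEO.pixel_mm, right + dx * GEO.pixel_mm, widths, GEO) > 0
            ap = extract_leaf_edges(BinaryAperture(mask, 1.0), GEO, widths)
            corrected = apply_offset_correction(ap, gantry, 0.0, model, GEO)
            for p in corrected.pairs:
                assert p.left_edge_mm == pytest.approx(-20.0, abs=0.5 * GEO.pixel_mm)
                assert p.right_edge_mm == pytest.approx(20.0, abs=0.5 * GEO.pixel_mm)


class TestApplyOffsetCorrection:
    def _aperture(self):
        return LeafAperture(0, [LeafPair(0, -10.0, 10.0, True), LeafPair(1, 0.0, 0.5, False)])

    def test_zero_model_is_identity(self):
        out = apply_offset_correction(self._aperture(), 123.0, 0.0, OffsetModel.zero(), GEO)
        assert out.pairs[0].left_edge_mm == -10.0
        assert out.pairs[0].right_edge_mm == 10.0

    def test_constant_offset_sign_convention(self):
        model = OffsetModel([0.0], [2.0], [2.0], [0.0], [0.0])
        out = apply_offset_correction(self._aperture(), 45.0, 0.0, model, GEO)
        # +2 px offset at 0.5 mm/px shifts edges by -1.0 mm
        assert out.pairs[0].left_edge_mm == pytest.approx(-11.0)
        assert out.pairs[0].right_edge_mm == pytest.approx(9.0)
        # closed pairs keep their park position
        assert out.pairs[1].left_edge_mm == 0.0

    def test_linear_interpolation_midpoint(self):
        model = OffsetModel([0.0, 30.0], [0.0, 2.0], [0.0, 2.0], [0.0, 0.0], [0.0, 0.0])
        assert model.cross_offsets_px(15.0, 0.0) == (1.0, 1.0)

    def test_collimator_outside_grid_rejected(self):
        fn = make_sinusoidal_shift_fn()
        model = measure_center_offsets(gen_offset_acquisition(shift_fn=fn, geometry=GEO))
        with pytest.raises(ApertureError, match="outside calibrated grid"):
            model.cross_offsets_px(0.0, 120.0)

    def test_json_roundtrip(self, tmp_path):
        fn = make_sinusoidal_shift_fn(amp_cross_px=2.0)
        model = measure_center_offsets(gen_offset_acquisition(shift_fn=fn, geometry=GEO))
        model.to_json(tmp_path / "m.json")
        back = OffsetModel.from_json(tmp_path / "m.json")
        assert back.sag_cross_left == model.sag_cross_left
        assert back.coll_shift_cross == model.coll_shift_cross
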