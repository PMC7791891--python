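"""Instance model: rasterization, IOU, label-map round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from immunoseg.model import (
    CellInstance,
    ImageFrame,
    InvariantError,
    LocalMask,
    iou,
    local_mask,
    mask_to_polygon,
    polygonize,
    rasterize,
    to_label_map,
    validate_cohort,
    validate_frame,
)
from immunoseg.simulate import dataset_config, generate_truth

from conftest import square_instance


class TestRasterize:
    def test_axis_aligned_square_sets_exactly_the_interior_centers(self, frame1024):
        mask = rasterize(square_instance(1, x0=0, y0=0, side=10), frame1024)
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_pixel_center_rule_matches_point_in_polygon_oracle(self, frame1024):
        # triangle with slanted edges; oracle = per-pixel center-in-polygon test
        tri = CellInstance(id=1, cell_class="pDC", outline=[(2.2, 1.1), (17.8, 4.3), (6.1, 15.7)])
        mask = rasterize(tri, frame1024)
        from shapely.geometry import Point, Polygon

        poly = Polygon(tri.outline)
        for i in range(20):
            for j in range(20):
                assert mask[i, j] == poly.contains(Point(j + 0.5, i + 0.5))

    def test_polygon_covering_whole_frame_sets_all_pixels(self):
        frame = ImageFrame(frame_id="f", width_px=32, height_px=32, pixel_size_um=1.0)
        inst = CellInstance(id=1, cell_class="CD4T",
                            outline=[(0, 0), (32, 0), (32, 32), (0, 32)])
        assert rasterize(inst, frame).all()

    def test_degenerate_two_vertex_polygon_rejected_with_id(self, frame1024):
        bad = CellInstance(id=7, cell_class="CD4T", outline=[(0, 0), (5, 5)])
        with pytest.raises(InvariantError, match="7"):
            rasterize(bad, frame1024)

    def test_zero_area_polygon_rejected(self, frame1024):
        bad = CellInstance(id=3, cell_class="CD4T", outline=[(1, 1), (5, 5), (9, 9)])
        with pytest.raises(InvariantError, match="3"):
            rasterize(bad, frame1024)


class TestIou:
    def test_identity_disjoint_and_partial_overlap(self):
        a = np.zeros((4, 4), bool)
        a[0:2, 0:2] = True
        assert iou(a, a) == 1.0
        b = np.zeros((4, 4), bool)
        b[2:4, 2:4] = True
        assert iou(a, b) == 0.0
        c = np.zeros((4, 4), bool)
        c[0:2, 1:3] = True  # overlaps a on a 2x1 strip
        assert iou(a, c) == pytest.approx(2 / 6)

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(3, 3\)"):
            iou(np.zeros((4, 4), bool), np.zeros((3, 3), bool))

    def test_empty_union_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_bounded_and_translation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) < 0.3
        b = rng.random((16, 16)) < 0.3
        if not (a.any() or b.any()):
            return
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        assert (v == 1.0) == bool(np.array_equal(a, b))
        # translate both masks together inside a larger frame
        big_a = np.zeros((24, 24), bool)
        big_b = np.zeros((24, 24), bool)
        big_a[5:21, 3:19] = a
        big_b[5:21, 3:19] = b
        assert iou(big_a, big_b) == pytest.approx(v)


class TestLabelMapRoundTrip:
    def test_empty_frame_gives_all_zero_image_and_empty_table(self):
        frame = ImageFrame(frame_id="f", width_px=16, height_px=16)
        labels, table = to_label_map(frame)
        assert not labels.any()
        assert len(table) == 0

    def test_disjoint_squares_roundtrip_preserves_labels_and_areas(self):
        frame = ImageFrame(
            frame_id="f", width_px=64, height_px=64, pixel_size_um=1.0,
            instances=[
                square_instance(1, "CD4T", 2, 2, 10),
                square_instance(2, "pDC", 20, 20, 8),
                square_instance(3, "Bcell", 40, 5, 12),
            ],
        )
        labels, table = to_label_map(frame)
        assert set(np.unique(labels)) == {0, 1, 2, 3}
        back = polygonize(labels, table, frame_id="f", pixel_size_um=1.0)
        assert len(back.instances) == 3
        for orig, rec in zip(frame.instances, back.instances):
            assert rec.id == orig.id
            assert rec.cell_class == orig.cell_class
            assert rec.confidence == orig.confidence
            assert np.array_equal(rasterize(rec, frame), rasterize(orig, frame))

    def test_overlap_raises_in_strict_mode_listing_ids(self):
        frame = ImageFrame(
            frame_id="f", width_px=32, height_px=32,
            instances=[square_instance(1, x0=2, y0=2), square_instance(2, x0=6, y0=6)],
        )
        with pytest.raises(InvariantError, match="1&2"):
            to_label_map(frame, mode="strict")

    def test_precedence_mode_gives_contested_pixels_to_higher_confidence(self):
        frame = ImageFrame(
            frame_id="f", width_px=32, height_px=32,
            instances=[
                square_instance(1, x0=2, y0=2, confidence=0.4, source="predicted"),
                square_instance(2, x0=6, y0=6, confidence=0.9, source="predicted"),
            ],
        )
        labels, _ = to_label_map(frame, mode="precedence")
        assert labels[8, 8] == 2  # center of the overlap strip
        assert labels[3, 3] == 1

    def test_missing_sidecar_label_raises_naming_it(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:4, 2:4] = 5
        import pandas as pd

        sidecar = pd.DataFrame({"label": [1], "class": ["CD4T"], "confidence": [1.0]})
        with pytest.raises(InvariantError, match="5"):
            polygonize(labels, sidecar)

    def test_all_zero_image_gives_empty_frame(self):
        import pandas as pd

        frame = polygonize(np.zeros((8, 8), dtype=np.int32),
                           pd.DataFrame(columns=["label", "class", "confidence"]))
        assert frame.instances == []

    def test_single_block_polygonizes_to_area_100(self):
        import pandas as pd

        labels = np.zeros((32, 32), dtype=np.int32)
        labels[4:14, 6:16] = 1
        sidecar = pd.DataFrame({"label": [1], "class": ["mDC"], "confidence": [0.8]})
        frame = polygonize(labels, sidecar, panel="panel2")
        (inst,) = frame.instances
        assert rasterize(inst, frame).sum() == 100

    def test_roundtrip_property_on_random_synthetic_frames(self):
        """Polygonize-then-rasterize reproduces every label's pixel set exactly."""
        cfg = dataset_config("FFPE_SS", n_frames=3, seed=11, frame_size_px=256,
                             cells_per_frame=8.0, aggregation=(3, 6.0))
        cohort = generate_truth(cfg)
        for frame in cohort.frames:
            labels, table = to_label_map(frame, mode="precedence")
            back = polygonize(labels, table, frame_id=frame.frame_id,
                              pixel_size_um=frame.pixel_size_um,
                              fixation=frame.fixation, panel=frame.panel)
            assert len(back.instances) == len(np.unique(labels)) - 1
            for inst in back.instances:
                assert np.array_equal(
                    rasterize(inst, frame), labels == inst.id
                )

    def test_repolygonization_is_idempotent_at_raster_level(self):
        cfg = dataset_config("fresh_frozen_DS", n_frames=1, seed=3, frame_size_px=256,
                             cells_per_frame=6.0)
        frame = generate_truth(cfg).frames[0]
        for inst in frame.instances:
            lm = local_mask(inst, frame)
            ring = mask_to_polygon(lm)
            assert ring is not None
            re_inst = CellInstance(id=inst.id, cell_class=inst.cell_class, outline=ring)
            assert np.array_equal(rasterize(re_inst, frame), rasterize(inst, frame))


class TestValidation:
    def test_manual_instance_must_have_unit_confidence(self):
        frame = ImageFrame(
            frame_id="f", width_px=32, height_px=32,
            instances=[square_instance(1, confidence=0.7, source="manual")],
        )
        with pytest.raises(InvariantError, match="confidence"):
            validate_frame(frame)

    def test_out_of_bounds_vertices_rejected(self):
        frame = ImageFrame(
            frame_id="f", width_px=16, height_px=16,
            instances=[square_instance(1, x0=10, y0=10, side=10)],
        )
        with pytest.raises(InvariantError, match="bounds"):
            validate_frame(frame)

    def test_cohort_with_mixed_pixel_sizes_rejected(self):
        from immunoseg.model import CohortDataset

        cohort = CohortDataset(
            name="c",
            frames=[
                ImageFrame(frame_id="a", pixel_size_um=0.1058),
                ImageFrame(frame_id="b", pixel_size_um=0.1413),
            ],
        )
        with pytest.raises(InvariantError, match="pixel size"):
            validate_cohort(cohort)
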