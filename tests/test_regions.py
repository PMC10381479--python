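import numpy as np
import pytest

from sulcuseg import (
    BinaryMask,
    CropWindow,
    ROIPolygon,
    filter_by_area,
    filter_by_centroid_in_roi,
    intersect_with_roi,
    label_components,
    points_in_polygon,
    rasterize_polygon,
    select_largest,
    to_original_frame,
)
from sulcuseg.errors import BoundsError, EmptySelectionError, FrameError

from oracles import flood_fill_label, shapely_point_in_polygon


def _mask(grid, window=None):
    return BinaryMask(np.asarray(grid), frame="crop", window=window)


class TestLabelComponents:
    def test_empty_mask(self):
        lr = label_components(_mask(np.zeros((6, 6), dtype=int)))
        assert lr.nregions == 0 and lr.records == []

    def test_full_mask_single_region(self):
        lr = label_components(_mask(np.ones((5, 7), dtype=int)))
        assert lr.nregions == 1
        assert lr.records[0].area == 35

    def test_diagonal_pixels_join_under_eight_connectivity(self):
        grid = np.zeros((4, 4), dtype=int)
        grid[1, 1] = grid[2, 2] = 1
        assert label_components(_mask(grid), connectivity=2).nregions == 1
        assert label_components(_mask(grid), connectivity=1).nregions == 2

    def test_agrees_with_flood_fill_oracle(self, rng):
        for _ in range(25):
            grid = rng.random((16, 16)) > 0.6
            lr = label_components(_mask(grid.astype(int)))
            assert np.array_equal(lr.label_image, flood_fill_label(grid))

    def test_area_conservation(self, rng):
        grid = rng.random((20, 20)) > 0.7
        lr = label_components(_mask(grid.astype(int)))
        assert sum(r.area for r in lr.records) == int(grid.sum())


class TestRegionFeatures:
    def test_square_block_centroid(self):
        grid = np.zeros((4, 4), dtype=int)
        grid[0:2, 0:2] = 1
        rec = label_components(_mask(grid)).records[0]
        assert rec.area == 4
        assert rec.centroid == (0.5, 0.5)

    def test_single_pixel(self):
        grid = np.zeros((8, 8), dtype=int)
        grid[3, 7] = 1
        rec = label_components(_mask(grid)).records[0]
        assert rec.area == 1 and rec.centroid == (3.0, 7.0)

    def test_l_shaped_region_centroid(self):
        grid = np.zeros((3, 3), dtype=int)
        grid[0, 0] = grid[1, 0] = grid[1, 1] = 1
        rec = label_components(_mask(grid)).records[0]
        assert rec.centroid[0] == pytest.approx(2 / 3)
        assert rec.centroid[1] == pytest.approx(1 / 3)

    def test_bbox_half_open(self):
        grid = np.zeros((6, 6), dtype=int)
        grid[2:4, 1:5] = 1
        rec = label_components(_mask(grid)).records[0]
        assert rec.bbox == CropWindow(2, 4, 1, 5)


class TestFilters:
    def _two_region_mask(self):
        grid = np.zeros((10, 10), dtype=int)
        grid[1:4, 1:5] = 1  # area 12
        grid[7:8, 6:9] = 1  # area 3
        return label_components(_mask(grid))

    def test_area_filter_drops_small_regions(self):
        lr = filter_by_area(self._two_region_mask(), 5)
        assert lr.nregions == 1
        assert lr.records[0].area == 12
        assert sum(r.area for r in lr.records) == int((lr.label_image > 0).sum())

    def test_zero_min_area_is_identity(self):
        lr = self._two_region_mask()
        out = filter_by_area(lr, 0)
        assert np.array_equal(out.label_image, lr.label_image)

    def test_overlarge_min_area_empties(self):
        lr = filter_by_area(self._two_region_mask(), 1000)
        assert lr.nregions == 0 and not lr.label_image.any()

    def test_labels_not_renumbered(self):
        grid = np.zeros((10, 10), dtype=int)
        grid[0, 0:2] = 1       # label 1, area 2
        grid[5, 0:8] = 1       # label 2, area 8
        lr = filter_by_area(label_components(_mask(grid)), 5)
        assert [r.label for r in lr.records] == [2]

    def test_centroid_filter_inside_and_outside(self):
        grid = np.zeros((10, 20), dtype=int)
        grid[4:6, 2:4] = 1    # centroid (4.5, 2.5) — inside the ROI below
        grid[4:6, 14:16] = 1  # centroid (4.5, 14.5) — outside
        window = CropWindow(0, 10, 0, 20)
        roi = ROIPolygon([(0, 0), (9, 0), (9, 9), (0, 9)])
        lr = filter_by_centroid_in_roi(label_components(_mask(grid)), roi, window)
        assert [r.centroid for r in lr.records] == [(4.5, 2.5)]

    def test_centroid_on_polygon_edge_kept(self):
        grid = np.zeros((8, 8), dtype=int)
        grid[2, 3:6] = 1  # centroid (2.0, 4.0): on the ROI's top edge y=2
        window = CropWindow(0, 8, 0, 8)
        roi = ROIPolygon([(1, 2), (7, 2), (7, 7), (1, 7)])
        assert shapely_point_in_polygon([(4.0, 2.0)], roi.as_array())[0]
        lr = filter_by_centroid_in_roi(label_components(_mask(grid)), roi, window)
        assert lr.nregions == 1

    def test_centroid_filter_respects_crop_offset(self):
        grid = np.zeros((6, 6), dtype=int)
        grid[2, 2] = 1  # crop-frame (2, 2) = original (12, 22)
        window = CropWindow(10, 16, 20, 26)
        inside = ROIPolygon([(21, 11), (25, 11), (25, 15), (21, 15)])
        outside = ROIPolygon([(0, 0), (5, 0), (5, 5)])
        lr = label_components(_mask(grid))
        assert filter_by_centroid_in_roi(lr, inside, window).nregions == 1
        assert filter_by_centroid_in_roi(lr, outside, window).nregions == 0


class TestSelectLargest:
    def test_picks_maximum_area(self):
        grid = np.zeros((12, 12), dtype=int)
        grid[0:3, 0:4] = 1   # 12
        grid[5:6, 0:7] = 1   # 7
        grid[9, 0:3] = 1     # 3
        sel = select_largest(label_components(_mask(grid)))
        assert sel.count() == 12
        assert sel.grid[1, 1] and not sel.grid[5, 1]

    def test_single_region_returned_as_is(self):
        grid = np.zeros((5, 5), dtype=int)
        grid[1:3, 1:3] = 1
        sel = select_largest(label_components(_mask(grid)))
        assert np.array_equal(sel.grid, grid.astype(bool))

    def test_equal_area_tie_breaks_to_lower_label(self):
        grid = np.zeros((7, 7), dtype=int)
        grid[0, 0:3] = 1  # label 1
        grid[4, 0:3] = 1  # label 2, same area
        sel = select_largest(label_components(_mask(grid)))
        assert sel.grid[0, 0] and not sel.grid[4, 0]

    def test_empty_labeling_raises_selection_failure(self):
        lr = label_components(_mask(np.zeros((4, 4), dtype=int)))
        with pytest.raises(EmptySelectionError):
            select_largest(lr)


class TestIntersectWithRoi:
    def test_mask_inside_roi_unchanged(self):
        grid = np.zeros((10, 10), dtype=int)
        grid[3:5, 3:5] = 1
        window = CropWindow(0, 10, 0, 10)
        roi = ROIPolygon([(0, 0), (9, 0), (9, 9), (0, 9)])
        out = intersect_with_roi(_mask(grid, window), roi, window)
        assert np.array_equal(out.grid, grid.astype(bool))

    def test_disjoint_mask_becomes_empty(self):
        grid = np.zeros((10, 10), dtype=int)
        grid[8:10, 8:10] = 1
        window = CropWindow(0, 10, 0, 10)
        roi = ROIPolygon([(0, 0), (4, 0), (4, 4), (0, 4)])
        assert intersect_with_roi(_mask(grid, window), roi, window).count() == 0

    def test_straddling_mask_clipped_per_pixel(self, rng):
        window = CropWindow(0, 12, 0, 12)
        roi = ROIPolygon([(2, 1), (10, 3), (8, 10), (1, 8)])
        grid = rng.random((12, 12)) > 0.5
        out = intersect_with_roi(_mask(grid.astype(int), window), roi, window)
        yy, xx = np.mgrid[0:12, 0:12]
        oracle = shapely_point_in_polygon(
            np.column_stack([xx.ravel(), yy.ravel()]), roi.as_array()
        ).reshape(12, 12)
        assert np.array_equal(out.grid, grid & oracle)

    def test_requires_crop_frame(self):
        mask = BinaryMask(np.ones((4, 4), dtype=int), frame="original")
        with pytest.raises(FrameError):
            intersect_with_roi(mask, ROIPolygon([(0, 0), (3, 0), (3, 3)]),
                               CropWindow(0, 4, 0, 4))


class TestToOriginalFrame:
    def test_vertex_offset(self):
        window = CropWindow(100, 150, 200, 260)
        out = to_original_frame(np.array([[20.0, 10.0]]), window, (550, 868))
        assert out.tolist() == [[220.0, 110.0]]

    def test_mask_reembedding_and_round_trip(self):
        window = CropWindow(3, 7, 2, 8)
        grid = np.zeros((4, 6), dtype=int)
        grid[1, 2] = 1
        full = to_original_frame(_mask(grid, window), window, (20, 20))
        assert full.frame == "original"
        assert full.grid[4, 4] and full.count() == 1
        back = full.grid[window.row_min:window.row_max, window.col_min:window.col_max]
        assert np.array_equal(back, grid.astype(bool))

    def test_window_at_origin_is_identity_shift(self):
        window = CropWindow(0, 5, 0, 5)
        verts = np.array([[1.5, 2.5], [3.0, 0.0]])
        assert np.array_equal(to_original_frame(verts, window, (5, 5)), verts)

    def test_out_of_bounds_rejected(self):
        window = CropWindow(18, 20, 18, 20)
        with pytest.raises(BoundsError):
            to_original_frame(np.array([[5.0, 5.0]]), window, (20, 20))


class TestPolygonGeometry:
    def test_matches_shapely_on_random_convex_polygons(self, rng):
        for _ in range(20):
            pts = rng.random((8, 2)) * 20
            from scipy.spatial import ConvexHull

            hull = ConvexHull(pts)
            verts = pts[hull.vertices]
            probes = rng.random((60, 2)) * 24 - 2
            ours = points_in_polygon(probes, verts)
            ref = shapely_point_in_polygon(probes, verts)
            assert np.array_equal(ours, ref)

    def test_rasterization_matches_pointwise_test(self, rng):
        verts = np.array([(1.0, 1.0), (14.0, 2.0), (12.0, 13.0), (3.0, 11.0)])
        grid = rasterize_polygon(verts, (16, 16))
        yy, xx = np.mgrid[0:16, 0:16]
        ref = shapely_point_in_polygon(
            np.column_stack([xx.ravel(), yy.ravel()]), verts
        ).reshape(16, 16)
        assert np.array_equal(grid, ref)

    def test_vertices_count_as_inside(self):
        verts = [(2, 2), (8, 2), (8, 8), (2, 8)]
        assert points_in_polygon([(2.0, 2.0), (8.0, 5.0)], verts).all()
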