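"""Segmentation-stage checks against synthetic ground truth."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fibrilmorph import (SegmentationParams, SyntheticImageSpec,
                         adaptive_threshold, apply_cell_mask, filter_objects,
                         generate_fibril_image, segment, split_touching)
from fibrilmorph.segmentation import BORDER, INTERIOR, LabelImage

from conftest import rasterize_disk, single_population


class TestCellMask:
    def test_empty_and_full_mask_areas(self):
        image = np.full((64, 64), 200, np.uint8)
        _, ac = apply_cell_mask(image, np.zeros_like(image, bool), nm_per_px=2.0)
        assert ac == 0.0
        _, ac = apply_cell_mask(image, np.ones_like(image, bool), nm_per_px=2.0)
        assert ac == 64 * 64 * 4.0
        assert apply_cell_mask(image, None)[1] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            apply_cell_mask(np.zeros((10, 10)), np.zeros((5, 5), bool))

    def test_cell_blob_area_matches_polygon(self):
        spec = SyntheticImageSpec(width_px=512, height_px=512, nm_per_px=2.0,
                                  diameter_mixture=single_population(),
                                  target_count=40, cell_fraction=0.15, seed=21)
        image, truth = generate_fibril_image(spec)
        from fibrilmorph.synthetic import _rasterize_polygons
        mask = _rasterize_polygons(truth.cell_polygons, spec)
        _, ac = apply_cell_mask(image, mask, spec.nm_per_px)
        poly_area = sum(p.area for p in truth.cell_polygons)
        assert ac == pytest.approx(poly_area, rel=0.02)


class TestAdaptiveThreshold:
    def test_recovers_disks_exactly_on_clean_image(self, clean_field):
        spec, image, truth = clean_field
        fg = adaptive_threshold(image, SegmentationParams())
        assert np.array_equal(fg, image == spec.foreground)

    def test_invariant_to_linear_shading(self, clean_field):
        spec, image, truth = clean_field
        shading = 0.8 + 0.4 * np.arange(image.shape[1]) / (image.shape[1] - 1)
        shaded = np.clip(np.round(image.astype(float) * shading), 0, 255)
        fg = adaptive_threshold(shaded, SegmentationParams())
        assert np.array_equal(fg, image == spec.foreground)

    def test_blank_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="contrast"):
            fg = adaptive_threshold(np.full((128, 128), 120.0), SegmentationParams())
        assert not fg.any()

    def test_masked_pixels_never_foreground(self, clean_field):
        spec, image, truth = clean_field
        mask = np.zeros(image.shape, bool)
        mask[:, :512] = True
        fg = adaptive_threshold(image, SegmentationParams(), cell_mask=mask)
        assert not fg[:, :512].any()

    def test_tile_size_validation(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((32, 32)), SegmentationParams(tile_size_px=64))


class TestSplitTouching:
    def test_disjoint_disks_two_labels(self):
        binary = rasterize_disk((128, 128), 30, 64, 15) | rasterize_disk((128, 128), 95, 64, 15)
        for ws in (False, True):
            lab = split_touching(binary, SegmentationParams(watershed_enabled=ws))
            assert lab.n_labels == 2

    def test_overlapping_disks_split_in_two(self):
        # equal disks, centres closer than 2r: overlap ~10% of radius
        r = 20
        binary = rasterize_disk((128, 128), 44, 64, r) | rasterize_disk((128, 128), 80, 64, r)
        lab = split_touching(binary, SegmentationParams(watershed_enabled=True,
                                                        watershed_footprint_px=21))
        assert lab.n_labels == 2
        sizes = np.bincount(lab.labels.ravel())[1:]
        assert sizes.min() / sizes.max() > 0.8  # split near the neck, not lopsided

    def test_single_disk_not_oversplit(self):
        binary = rasterize_disk((128, 128), 64, 64, 25)
        lab = split_touching(binary, SegmentationParams(watershed_enabled=True))
        assert lab.n_labels == 1


class TestFilterObjects:
    def test_border_and_interior_classes(self):
        binary = rasterize_disk((128, 128), 64, 64, 15) | rasterize_disk((128, 128), 2, 64, 15)
        lab = split_touching(binary, SegmentationParams())
        filtered = filter_objects(lab, SegmentationParams(min_area_nm2=10), 1.0)
        assert sorted(filtered.classes.values()) == [BORDER, INTERIOR]

    def test_small_speck_removed(self):
        binary = rasterize_disk((128, 128), 64, 64, 15)
        binary[10, 10] = True
        lab = split_touching(binary, SegmentationParams())
        filtered = filter_objects(lab, SegmentationParams(min_area_nm2=50,
                                                          opening_radius_px=0), 1.0)
        assert filtered.n_labels == 1

    def test_irregular_object_removed_by_solidity(self):
        # L-shape: solidity (area / convex hull area) well below 0.9
        binary = np.zeros((128, 128), bool)
        binary[20:100, 20:32] = True
        binary[88:100, 20:100] = True
        area = binary.sum()
        # brute-force solidity oracle from the convex hull of pixel centres
        from scipy.spatial import ConvexHull
        pts = np.argwhere(binary) + 0.5
        hull_area = ConvexHull(pts).volume
        assert area / hull_area < 0.55
        lab = split_touching(binary, SegmentationParams())
        filtered = filter_objects(lab, SegmentationParams(min_solidity=0.9,
                                                          opening_radius_px=0), 1.0)
        assert filtered.n_labels == 0

    def test_disk_survives_default_filters(self):
        binary = rasterize_disk((128, 128), 64, 64, 15)
        lab = split_touching(binary, SegmentationParams())
        filtered = filter_objects(lab, SegmentationParams(), nm_per_px=4.0)
        assert filtered.n_labels == 1


class TestEndToEnd:
    def test_interior_count_and_centroids_match_truth(self, clean_field_segmented):
        spec, image, truth, labels, _ = clean_field_segmented
        interior_truth = truth.interior_mask_raster(
            spec.nm_per_px, spec.width_px, spec.height_px)
        assert len(labels.labels_of_class(INTERIOR)) == interior_truth.sum()
        # every interior ground-truth disk has a detected centroid within 1 px
        from fibrilmorph import measure
        records = [r for r in measure(labels, spec.nm_per_px) if not r.border]
        found = np.array([r.centroid_nm for r in records])
        dist, _ = cKDTree(found).query(truth.centroids_nm[interior_truth])
        assert dist.max() < spec.nm_per_px  # < 1 px

    def test_touching_field_count_within_2pct(self):
        spec = SyntheticImageSpec(width_px=1024, height_px=1024, nm_per_px=4.0,
                                  diameter_mixture=single_population(),
                                  min_gap_nm=0.0, allow_touching=True,
                                  target_count=200, noise_sd=8.0, seed=6)
        image, truth = generate_fibril_image(spec)
        labels, _ = segment(image, SegmentationParams(watershed_enabled=True),
                            spec.nm_per_px)
        assert abs(labels.n_labels - truth.n) <= 0.02 * truth.n

    def test_inversion_convention_flag(self, clean_field):
        spec, image, truth = clean_field
        normal, _ = segment(image, SegmentationParams(), spec.nm_per_px)
        inverted, _ = segment(255 - image, SegmentationParams(dark_fibrils=False),
                              spec.nm_per_px)
        assert np.array_equal(normal.labels > 0, inverted.labels > 0)
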