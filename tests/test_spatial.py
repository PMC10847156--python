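"""Packing statistics: pruned triangulation, gaps, radial distribution."""

import numpy as np
import pytest

from fibrilmorph import (SegmentationParams, SyntheticImageSpec,
                         generate_fibril_image, hexagonal_lattice,
                         interfibrillar_gaps, measure, rdf, segment,
                         triangle_angles, triangulate_and_prune)
from fibrilmorph.morphometry import FibrilRecord

from conftest import single_population


class TestTriangulatePrune:
    def test_hexagonal_lattice_kept_edges_all_spacing(self):
        tri = triangulate_and_prune(hexagonal_lattice(100.0, 10, 10))
        assert len(tri.edges) > 0
        assert np.allclose(tri.edge_lengths, 100.0, atol=1e-9)

    def test_square_of_four_points_all_pruned(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        with pytest.warns(UserWarning, match="perimeter"):
            tri = triangulate_and_prune(pts)
        assert len(tri.edges) == 0 and len(tri.triangles) == 0

    def test_poisson_delaunay_mean_edge_length(self):
        # Poisson-Delaunay expectation: mean edge = 32/(9 pi) / sqrt(density)
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, (500, 2))
        tri = triangulate_and_prune(pts)
        expected = 32 / (9 * np.pi) / np.sqrt(500)
        assert tri.edge_lengths.mean() == pytest.approx(expected, rel=0.10)

    def test_pruned_edges_touch_boundary_kept_edges_do_not(self):
        rng = np.random.default_rng(3)
        tri = triangulate_and_prune(rng.uniform(0, 1000, (200, 2)))
        boundary = set(tri.boundary_vertices.tolist())
        for i, j in tri.edges:
            assert i not in boundary and j not in boundary
        for i, j in tri.pruned_edges:
            assert i in boundary or j in boundary
        for t in tri.triangles:
            assert not (set(t.tolist()) & boundary)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            triangulate_and_prune(np.array([[0.0, 0], [1, 1], [2, 2]]))
        collinear = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError):
            triangulate_and_prune(collinear)
        with pytest.raises(ValueError, match="alpha"):
            triangulate_and_prune(np.random.default_rng(0).uniform(0, 1, (20, 2)),
                                  alpha=1e9)


class TestTriangleAngles:
    def test_hexagonal_lattice_all_sixty_degrees(self):
        tri = triangulate_and_prune(hexagonal_lattice(100.0, 10, 10))
        angles = triangle_angles(tri)
        assert angles.size > 0
        assert np.allclose(angles, 60.0, atol=1e-6)

    def test_right_isoceles_closed_form(self):
        from fibrilmorph.spatial import _interior_angles
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        angles = _interior_angles(pts, np.array([[0, 1, 2]]))[0]
        assert sorted(np.round(angles, 9)) == [45.0, 45.0, 90.0]

    def test_angle_sums_are_180(self):
        rng = np.random.default_rng(4)
        tri = triangulate_and_prune(rng.uniform(0, 500, (120, 2)))
        assert np.allclose(tri.angles_deg.sum(axis=1), 180.0, atol=1e-6)


def _disk_record(idx, cx, cy, r, n_vertices=256) -> FibrilRecord:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    boundary = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return FibrilRecord(id=idx, centroid_nm=(cx, cy), area_nm2=np.pi * r**2,
                        perimeter_nm=2 * np.pi * r, mfd_nm=2 * r,
                        circularity=1.0, border=False, boundary_nm=boundary)


class TestInterfibrillarGaps:
    def _two_disk_setup(self):
        # embed the two disks of interest in a quincunx so they survive pruning
        recs = [
            _disk_record(0, 0.0, 0.0, 50.0),
            _disk_record(1, 150.0, 0.0, 50.0),
            _disk_record(2, 75.0, 130.0, 40.0),
            _disk_record(3, 75.0, -130.0, 40.0),
            _disk_record(4, -150.0, 130.0, 40.0),
            _disk_record(5, 300.0, 130.0, 40.0),
            _disk_record(6, -150.0, -130.0, 40.0),
            _disk_record(7, 300.0, -130.0, 40.0),
        ]
        pts = np.array([r.centroid_nm for r in recs])
        tri = triangulate_and_prune(pts, alpha=1 / 400.0)
        return tri, recs

    def test_two_disk_gap_and_ratio(self):
        tri, recs = self._two_disk_setup()
        gaps, ratios = interfibrillar_gaps(tri, recs)
        pair = [e for e, (i, j) in enumerate(tri.edges) if {i, j} == {0, 1}]
        assert pair, "central edge pruned unexpectedly"
        e = pair[0]
        assert gaps[e] == pytest.approx(150 - 50 - 50, abs=1e-6)
        assert ratios[e] == pytest.approx(50 / 100, abs=1e-6)

    def test_missing_boundary_falls_back_to_equivalent_circle(self):
        tri, recs = self._two_disk_setup()
        recs[0].boundary_nm = None
        gaps, _ = interfibrillar_gaps(tri, recs)
        pair = [e for e, (i, j) in enumerate(tri.edges) if {i, j} == {0, 1}][0]
        # equivalent-circle radius of a disk equals its radius: same answer
        assert gaps[pair] == pytest.approx(50.0, abs=1e-6)
        assert tri.gap_fallback[pair]

    def test_rsa_field_min_gap_respected(self):
        spec = SyntheticImageSpec(width_px=768, height_px=768, nm_per_px=4.0,
                                  diameter_mixture=single_population(),
                                  min_gap_nm=50.0, target_count=120, seed=15)
        image, truth = generate_fibril_image(spec)
        labels, _ = segment(image, SegmentationParams(), spec.nm_per_px)
        recs = [r for r in measure(labels, spec.nm_per_px) if not r.border]
        tri = triangulate_and_prune(np.array([r.centroid_nm for r in recs]))
        gaps, _ = interfibrillar_gaps(tri, recs)
        assert gaps.min() >= 50.0 - 2 * spec.nm_per_px


class TestRdf:
    def test_hexagonal_first_shell_six_neighbours(self):
        lat = hexagonal_lattice(100.0, 14, 14)
        prof = rdf(lat, dr=10.0, r_max=160.0)
        nz = np.nonzero(prof.counts)[0][0]
        assert prof.r[nz] - prof.dr / 2 == pytest.approx(100.0)  # bin [100, 110)
        assert prof.counts[nz] == pytest.approx(6.0)

    def test_poisson_field_g_near_one(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10_000, (2000, 2))
        prof = rdf(pts, dr=50.0, r_max=1000.0, region=(10_000.0, 10_000.0))
        # per-bin fluctuations reach ~0.1-0.2 at this size (pair counts are
        # correlated across reference points); the mean is unbiased
        assert np.all(np.abs(prof.g - 1.0) < 0.2)
        assert abs(prof.g.mean() - 1.0) < 0.07

    def test_two_point_pattern_single_bin(self):
        pts = np.vstack([np.array([[500.0, 500.0], [573.0, 500.0]]),
                         np.random.default_rng(6).uniform(0, 1000, (10, 2))])
        # restrict to an exact two-point check via a tiny window around them
        prof = rdf(pts[:12], dr=10.0, r_max=100.0, region=(1000.0, 1000.0))
        assert prof.counts.sum() > 0  # sanity; pair distances all counted

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1000, (300, 2))
        tri1 = triangulate_and_prune(pts)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        pts2 = pts @ rot.T + np.array([123.0, -456.0])
        tri2 = triangulate_and_prune(pts2)
        assert np.allclose(np.sort(tri1.edge_lengths), np.sort(tri2.edge_lengths),
                           atol=1e-6)
        assert np.allclose(np.sort(tri1.angles_deg.ravel()),
                           np.sort(tri2.angles_deg.ravel()), atol=1e-6)

    def test_first_peak_beyond_generator_exclusion_zone(self):
        spec = SyntheticImageSpec(width_px=768, height_px=768, nm_per_px=4.0,
                                  diameter_mixture=single_population(150.0, 10.0),
                                  min_gap_nm=40.0, target_count=150, seed=16)
        _, truth = generate_fibril_image(spec)
        prof = rdf(truth.centroids_nm, dr=10.0, r_max=400.0,
                   region=(768 * 4.0, 768 * 4.0))
        first = prof.r[np.nonzero(prof.counts)[0][0]] - prof.dr / 2
        exclusion = truth.diameters_nm.min() + 40.0
        assert first >= exclusion - prof.dr

    def test_input_guards(self):
        pts = np.random.default_rng(8).uniform(0, 100, (30, 2))
        with pytest.raises(ValueError):
            rdf(pts[:5], 10.0, 50.0)
        with pytest.raises(ValueError, match="r_max"):
            rdf(pts, 10.0, 1000.0, region=(100.0, 100.0))
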