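"""Plane families, plane-triangle intersection, contour chaining, resampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchpath import (
    Plane,
    PatchSpec,
    SurfacePolyline,
    TriangleMesh,
    build_plane_family,
    intersect_plane_triangle,
    make_wavy_patch,
    resample_polyline,
    slice_mesh,
    slice_mesh_family,
)
from patchpath.slicer import SliceError, _chain_segments

from conftest import point_to_mesh_distance

X = np.array([1.0, 0.0, 0.0])
TRI = np.array([(0, 0, 0), (2, 0, 0), (0, 2, 0)], dtype=float)


class TestPlaneFamily:
    def test_unit_spacing_gives_interior_planes(self):
        fam = build_plane_family(np.array([[0, 0, 0], [10, 10, 5]]), "x", 1.0)
        np.testing.assert_allclose(fam.offsets, np.arange(1, 10))

    def test_coarse_spacing(self):
        fam = build_plane_family(np.array([[0, 0, 0], [10, 10, 5]]), "y", 4.0)
        np.testing.assert_allclose(fam.offsets, [4.0, 8.0])

    def test_span_not_exceeding_spacing_is_an_error(self):
        with pytest.raises(SliceError):
            build_plane_family(np.array([[0, 0, 0], [1, 1, 1]]), "x", 2.0)

    @given(lo=st.floats(-50, 50), span=st.floats(2.1, 80), spacing=st.floats(0.3, 2))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_offsets_strictly_inside_and_uniform(self, lo, span, spacing):
        bounds = np.array([[lo, 0, 0], [lo + span, 1, 1]])
        fam = build_plane_family(bounds, "x", spacing)
        assert fam.offsets[0] > lo
        assert fam.offsets[-1] < lo + span
        if len(fam.offsets) > 1:
            np.testing.assert_allclose(np.diff(fam.offsets), spacing, atol=1e-9)


class TestPlaneTriangle:
    def test_analytic_crossing(self):
        seg = intersect_plane_triangle(Plane(X, 1.0), TRI)
        np.testing.assert_allclose(
            sorted(seg.tolist()), [[1, 0, 0], [1, 1, 0]], atol=1e-12
        )

    def test_disjoint_plane(self):
        assert intersect_plane_triangle(Plane(X, 3.0), TRI) is None

    def test_coplanar_edge_suppressed(self):
        # the x = 0 plane contains one edge of the triangle: no segment
        assert intersect_plane_triangle(Plane(X, 0.0), TRI) is None

    def test_vertex_touch_suppressed(self):
        # plane through the apex vertex only
        assert intersect_plane_triangle(Plane(X, 2.0), TRI) is None

    def test_fully_coplanar_triangle_suppressed(self):
        flat = np.array([(1, 0, 0), (1, 1, 0), (1, 0, 1)], dtype=float)
        assert intersect_plane_triangle(Plane(X, 1.0), flat) is None

    def test_degenerate_triangle_rejected(self):
        bad = np.array([(0, 0, 0), (1, 0, 0), (2, 0, 0)], dtype=float)
        with pytest.raises(SliceError):
            intersect_plane_triangle(Plane(X, 0.5), bad)

    def test_endpoints_on_plane_and_inside_triangle(self):
        seg = intersect_plane_triangle(Plane(X, 0.7), TRI)
        assert np.abs(seg @ X - 0.7).max() < 1e-9
        # barycentric membership
        for p in seg:
            A = np.column_stack([TRI[1] - TRI[0], TRI[2] - TRI[0]])
            uv, *_ = np.linalg.lstsq(A, p - TRI[0], rcond=None)
            assert -1e-9 <= uv[0] and -1e-9 <= uv[1] and uv.sum() <= 1 + 1e-9


class TestSliceMesh:
    def test_flat_plate_single_spanning_polyline(self, flat_plate_10):
        polys = slice_mesh(flat_plate_10, Plane(X, 5.0))
        assert len(polys) == 1
        pts = polys[0].points
        assert pts[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert pts[-1, 1] == pytest.approx(10.0, abs=1e-9)
        assert np.abs(pts[:, 2]).max() < 1e-12
        assert np.abs(pts[:, 0] - 5.0).max() < 1e-9

    def test_cap_contour_lies_on_sphere(self, cap_mesh):
        # Intersection points sit on triangle edges whose endpoints are on the
        # sphere, so the sphere residual is bounded by the chordal sagitta
        # L^2 / 8R of the longest mesh edge.
        R, a = 25.0, 10.0
        center = np.array([0.0, 0.0, (R - math.sqrt(R**2 - a**2)) - R])
        edges = cap_mesh.vertices[cap_mesh.faces]
        edge_len = np.linalg.norm(
            edges - np.roll(edges, 1, axis=1), axis=2
        ).max()
        polys = slice_mesh(cap_mesh, Plane(X, 0.0))  # through the apex
        assert polys
        pts = np.vstack([p.points for p in polys])
        d = np.linalg.norm(pts - center, axis=1)
        assert np.abs(d - R).max() <= edge_len**2 / (8 * R) + 1e-12

    def test_disconnected_components_give_separate_polylines(self):
        # two plates 10 mm apart in y, crossed by one x-plane
        v = np.array([(0, 0, 0), (4, 0, 0), (0, 4, 0), (4, 4, 0),
                      (0, 14, 0), (4, 14, 0), (0, 18, 0), (4, 18, 0)], dtype=float)
        f = np.array([(0, 1, 3), (0, 3, 2), (4, 5, 7), (4, 7, 6)])
        mesh = TriangleMesh(v, f)
        polys = slice_mesh(mesh, Plane(X, 2.0))
        assert len(polys) == 2

    def test_chaining_conserves_segments(self, cap_mesh):
        plane = Plane(X, 3.0)
        faces = cap_mesh.faces[cap_mesh.face_normals[:, 2] > 0]
        n_segments = sum(
            1
            for fc in faces
            if intersect_plane_triangle(plane, cap_mesh.vertices[fc]) is not None
        )
        polys = slice_mesh(cap_mesh, plane)
        assert sum(len(p.points) - 1 for p in polys) == n_segments

    def test_points_ordered_monotonically_along_sweep(self, wavy_mesh):
        for poly in slice_mesh_family(
            wavy_mesh, build_plane_family(wavy_mesh.bounds, "x", 1.0)
        ):
            assert (np.diff(poly.points[:, 1]) > 0).all()

    def test_polylines_lie_on_mesh_surface(self, wavy_mesh):
        """Oracle: brute-force point-to-triangle distance, independent of slicing."""
        polys = slice_mesh_family(
            wavy_mesh, build_plane_family(wavy_mesh.bounds, "y", 2.0)
        )
        pts = np.vstack([p.points for p in polys])
        sub = pts[:: max(1, len(pts) // 120)]
        assert point_to_mesh_distance(sub, wavy_mesh).max() < 1e-6

    def test_total_length_rigid_translation_equivariance(self, cap_mesh):
        def total_length(mesh, offset):
            fam = build_plane_family(mesh.bounds, "x", 2.0)
            return sum(p.length for p in slice_mesh_family(mesh, fam))

        base = total_length(cap_mesh, 0.0)
        shifted = total_length(cap_mesh.translated((7.3, -2.1, 4.0)), 0.0)
        assert shifted == pytest.approx(base, abs=1e-6)

    def test_against_trimesh_section_oracle(self, cap_mesh):
        """Independent slicing oracle: trimesh's plane section, same total length."""
        trimesh = pytest.importorskip("trimesh")
        tm = trimesh.Trimesh(vertices=cap_mesh.vertices, faces=cap_mesh.faces,
                             process=False)
        for offset in (0.0, 3.0, -6.5):
            section = tm.section(plane_origin=[offset, 0, 0], plane_normal=[1, 0, 0])
            ours = slice_mesh(cap_mesh, Plane(X, offset))
            assert section is not None
            assert sum(p.length for p in ours) == pytest.approx(
                section.length, abs=1e-6
            )


class TestResample:
    def test_ten_mm_line_at_benchmark_step(self):
        poly = SurfacePolyline([(0, 0, 0), (0, 10, 0)], Plane(X, 0.0))
        out = resample_polyline(poly, 2.09)
        assert len(out.points) == 6  # ceil(10/2.09) = 5 subdivisions
        np.testing.assert_allclose(
            np.linalg.norm(np.diff(out.points, axis=0), axis=1), 2.0, atol=1e-12
        )

    def test_compliant_polyline_returned_unchanged(self):
        poly = SurfacePolyline([(0, 0, 0), (0, 1, 0), (0, 2, 0)], Plane(X, 0.0))
        assert resample_polyline(poly, 2.09) is poly

    def test_large_step_keeps_existing_points(self):
        poly = SurfacePolyline([(0, 0, 0), (0, 3, 0), (0, 7, 0)], Plane(X, 0.0))
        out = resample_polyline(poly, 100.0)
        np.testing.assert_array_equal(out.points, poly.points)

    def test_single_point_rejected(self):
        poly = SurfacePolyline(np.zeros((1, 3)), Plane(X, 0.0))
        with pytest.raises(SliceError):
            resample_polyline(poly, 1.0)

    @given(
        step=st.floats(0.11, 3.0),
        ys=st.lists(
            st.integers(-200, 200).map(lambda v: v / 10.0),
            min_size=2, max_size=6, unique=True,
        ),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_resampled_points_lie_on_original_polyline(self, step, ys):
        pts = np.array([[0.0, y, 0.5 * y] for y in sorted(ys)])
        poly = SurfacePolyline(pts, Plane(X, 0.0))
        out = resample_polyline(poly, step)
        # endpoints preserved
        np.testing.assert_allclose(out.points[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(out.points[-1], pts[-1], atol=1e-12)
        # spacing bound
        gaps = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        assert gaps.max() <= step + 1e-9
        # every new point sits on some original segment (zero chord error)
        for p in out.points:
            dists = []
            for a, b in zip(pts[:-1], pts[1:]):
                ab = b - a
                t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                dists.append(np.linalg.norm(p - (a + t * ab)))
            assert min(dists) < 1e-9


def test_chain_handles_shuffled_segments():
    """Chaining reassembles one polyline from arbitrarily ordered segments."""
    rng = np.random.default_rng(11)
    ys = np.linspace(0, 8, 9)
    segs = [np.array([[1.0, ys[i], 0.0], [1.0, ys[i + 1], 0.0]]) for i in range(8)]
    rng.shuffle(segs)
    chains = _chain_segments(segs, Plane(X, 1.0))
    assert len(chains) == 1
    assert len(chains[0]) == 9
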