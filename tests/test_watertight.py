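"""Boundary detection/classification and shell closure."""

import numpy as np
import pytest

from respivox import (
    BoundarySet,
    FrameCloud,
    WatertightCloud,
    WatertightParams,
    assemble_watertight,
    build_back,
    build_walls,
    classify_boundary,
    compute_volume,
    detect_boundary,
    make_watertight,
    voxelize_solid,
)
from respivox.errors import ClassificationError, GeometryError, InsufficientPointsError, OpenShellError

from conftest import fibonacci_dome, fibonacci_sphere, planar_grid


class TestDetectBoundary:
    def test_grid_interior_edges_and_corners(self):
        pts = planar_grid(12, 12)
        bset = detect_boundary(FrameCloud(points=pts), k=8, angle_gap_thresh=np.pi / 2)
        on_edge = (
            (pts[:, 0] == 0) | (pts[:, 0] == 11) | (pts[:, 1] == 0) | (pts[:, 1] == 11)
        )
        # every interior node has a symmetric 8-neighborhood (max gap pi/4)
        assert not np.intersect1d(bset.all, np.flatnonzero(~on_edge)).size
        # all edge nodes (gap >= pi) and corners (gap 3 pi/2) are detected
        assert np.all(np.isin(np.flatnonzero(on_edge), bset.all))

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientPointsError):
            detect_boundary(FrameCloud(points=np.zeros((2, 3))), k=4)

    def test_closed_sphere_has_nearly_no_boundary(self):
        pts = fibonacci_sphere(4000, radii=(50.0, 50.0, 50.0))
        bset = detect_boundary(FrameCloud(points=pts))
        assert len(bset.all) < 0.01 * len(pts)

    def test_dome_rim_detected(self):
        pts = fibonacci_dome(3000)
        bset = detect_boundary(FrameCloud(points=pts), k=16, angle_gap_thresh=0.8 * np.pi)
        rim = pts[bset.all]
        assert len(bset.all) > 20
        # detected points concentrate at the z ~ 0 rim
        assert np.quantile(rim[:, 2], 0.9) < 0.15 * pts[:, 2].max()


class TestClassifyBoundary:
    def rect_patch(self):
        pts = planar_grid(30, 10)
        edge = (
            (pts[:, 0] == 0) | (pts[:, 0] == 29) | (pts[:, 1] == 0) | (pts[:, 1] == 9)
        )
        return FrameCloud(points=pts), np.flatnonzero(edge)

    def test_rectangle_partition(self):
        cloud, qb = self.rect_patch()
        bset = classify_boundary(cloud, qb, body_axis="x", quantiles=(0.15, 0.85))
        pts = cloud.points
        assert np.all(pts[bset.shoulder, 0] > pts[bset.waist, 0].max())
        assert np.all(pts[bset.end, 0] < pts[bset.waist, 0].min())
        union = np.sort(np.concatenate([bset.shoulder, bset.waist, bset.end]))
        np.testing.assert_array_equal(union, np.sort(qb))

    def test_reversed_axis_swaps_shoulder_and_end(self):
        cloud, qb = self.rect_patch()
        a = classify_boundary(cloud, qb, body_axis="x", quantiles=(0.15, 0.85))
        b = classify_boundary(cloud, qb, body_axis="-x", quantiles=(0.15, 0.85))
        np.testing.assert_array_equal(np.sort(a.shoulder), np.sort(b.end))
        np.testing.assert_array_equal(np.sort(a.end), np.sort(b.shoulder))
        np.testing.assert_array_equal(np.sort(a.waist), np.sort(b.waist))

    def test_empty_boundary_raises(self):
        cloud, _ = self.rect_patch()
        with pytest.raises(ClassificationError):
            classify_boundary(cloud, np.array([], dtype=int))


class TestBuildBack:
    def test_planar_patch_projection(self):
        pts = planar_grid(10, 10)
        pts[:, 2] = 100.0
        back, plane_z = build_back(FrameCloud(points=pts), offset=50.0)
        assert plane_z == 50.0
        assert np.all(back[:, 2] == 50.0)
        np.testing.assert_array_equal(back[:, :2], pts[:, :2])
        assert len(back) == len(pts)

    def test_dome_back_is_exact_xy_footprint(self):
        pts = fibonacci_dome(500)
        back, _ = build_back(FrameCloud(points=pts), offset=30.0)
        np.testing.assert_array_equal(back[:, :2], pts[:, :2])

    def test_explicit_plane_override(self):
        pts = planar_grid(5, 5)
        back, plane_z = build_back(FrameCloud(points=pts), offset=50.0, plane_z=-70.0)
        assert plane_z == -70.0 and np.all(back[:, 2] == -70.0)


class TestBuildWalls:
    def single_point_bset(self, cloud):
        return BoundarySet(
            all=np.array([0]),
            shoulder=np.array([0]),
            waist=np.array([], dtype=int),
            end=np.array([], dtype=int),
        )

    def test_interpolation_count_and_spacing(self):
        plane_z, spacing = 0.0, 5.0
        cloud = FrameCloud(points=[[10.0, 20.0, 4 * spacing]])
        bset = self.single_point_bset(cloud)
        shoulder, end, waist = build_walls(cloud, bset, plane_z, layer_spacing=spacing)
        assert len(shoulder) == 3 and len(end) == 0 and len(waist) == 0
        np.testing.assert_allclose(sorted(shoulder[:, 2]), [5.0, 10.0, 15.0])
        np.testing.assert_array_equal(shoulder[:, :2], [[10.0, 20.0]] * 3)

    def test_adjacent_layers_interpolate_nothing(self):
        cloud = FrameCloud(points=[[0.0, 0.0, 5.0]])
        shoulder, _, _ = build_walls(cloud, self.single_point_bset(cloud), 0.0, layer_spacing=5.0)
        assert len(shoulder) == 0

    def test_wall_points_stay_between_plane_and_boundary(self):
        pts = fibonacci_dome(2000)
        cloud = FrameCloud(points=pts)
        bset = detect_boundary(cloud, k=16, angle_gap_thresh=0.8 * np.pi)
        bset = classify_boundary(cloud, bset.all)
        for style in ("drop", "arc"):
            walls = build_walls(cloud, bset, plane_z=-40.0, layer_spacing=5.0, waist_style=style)
            for w in walls:
                if len(w):
                    assert w[:, 2].min() >= -40.0 - 1e-9
                    assert w[:, 2].max() <= pts[bset.all, 2].max() + 1e-9

    def test_boundary_below_plane_raises(self):
        cloud = FrameCloud(points=[[0.0, 0.0, -10.0]])
        with pytest.raises(GeometryError):
            build_walls(cloud, self.single_point_bset(cloud), plane_z=0.0)


class TestClosure:
    @pytest.mark.parametrize("resolution", [5.0, 10.0])
    @pytest.mark.parametrize("style", ["drop", "arc"])
    def test_dome_shell_passes_leak_test(self, resolution, style):
        cloud = FrameCloud(points=fibonacci_dome(3000))
        params = WatertightParams(waist_style=style)
        wc = make_watertight(cloud, params)
        grid = voxelize_solid(wc, resolution=resolution)
        # closed shell: the solid contains at least the analytic interior
        # (half-ellipsoid dome + slab down to the back plane); a leak would
        # collapse the volume to the thin shell band (< 0.6e6 mm^3)
        analytic = 2 / 3 * np.pi * 80 * 60 * 50 + np.pi * 80 * 60 * abs(wc.plane_z)
        assert compute_volume(grid) > 0.9 * analytic

    def test_surface_only_shell_fails_leak_test(self):
        pts = fibonacci_dome(3000)
        wc = WatertightCloud(
            surface=FrameCloud(points=pts),
            back=np.array([[0.0, 0.0, -40.0]]),  # a token floor: shell is open
            shoulder_wall=np.empty((0, 3)),
            end_wall=np.empty((0, 3)),
            waist_wall=np.empty((0, 3)),
            plane_z=-40.0,
        )
        with pytest.raises(OpenShellError) as exc:
            voxelize_solid(wc, resolution=5.0)
        assert exc.value.leak_voxel is not None

    def test_assemble_is_idempotent(self):
        cloud = FrameCloud(points=fibonacci_dome(1000))
        wc1 = make_watertight(cloud)
        wc2 = make_watertight(cloud)
        np.testing.assert_array_equal(wc1.all_points(), wc2.all_points())
        np.testing.assert_array_equal(wc1.component_labels(), wc2.component_labels())

    def test_component_labels_cover_all_points(self):
        wc = make_watertight(FrameCloud(points=fibonacci_dome(1500)))
        labels = wc.component_labels()
        assert len(labels) == len(wc.all_points())
        assert set(np.unique(labels)) <= {0, 1, 2, 3, 4}
        assert np.all(wc.back[:, 2] == wc.plane_z)
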