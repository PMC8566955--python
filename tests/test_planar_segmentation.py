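import numpy as np
import pytest

from ddft3d import (
    LabelVolume,
    PlanarStack,
    SliceContour,
    apply_signal_inclusion,
    extract_surface,
    interpolate_stack,
    livewire_contour,
)
from ddft3d.planar_segmentation import _dijkstra_path, _gradient_cost
from ddft3d.synthetic_phantom import BACKGROUND, HYPERINTENSE, HYPOINTENSE


def circle_mask(h, w, r, center=None, spacing=1.0):
    c = center or (h * spacing / 2, w * spacing / 2)
    rr, cc = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    return (rr * spacing - c[0]) ** 2 + (cc * spacing - c[1]) ** 2 <= r**2


class TestLivewire:
    def test_disk_edge_traced_within_one_pixel(self):
        """The lasso snaps to a sharp circular boundary."""
        # disk centered on pixel index (49, 49)
        img = circle_mask(100, 100, 40, (49.5, 49.5)).astype(float)
        seeds = [(89, 49), (49, 89), (9, 49), (49, 9)]
        contour = livewire_contour(img, seeds)
        r = np.hypot(contour.points[:, 0] - 49.0, contour.points[:, 1] - 49.0)
        assert np.abs(r - 40).max() <= 1.0

    def test_uniform_image_paths_are_minimal_lattice_paths(self):
        img = np.ones((30, 30))
        seeds = [(0, 0), (0, 20), (10, 20)]
        contour = livewire_contour(img, seeds)

        def geodesic(a, b):
            dx, dy = abs(a[0] - b[0]), abs(a[1] - b[1])
            return np.sqrt(2) * min(dx, dy) + abs(dx - dy)

        legs = list(zip(seeds, seeds[1:] + seeds[:1]))
        expected = (1 + 1e-3) * sum(geodesic(a, b) for a, b in legs)
        assert contour.path_cost == pytest.approx(expected, rel=1e-9)

    def test_path_cost_matches_exhaustive_dijkstra(self):
        """Independent scipy shortest-path oracle on a random 20x20 image."""
        import scipy.sparse as sp
        from scipy.sparse.csgraph import dijkstra

        rng = np.random.default_rng(0)
        img = rng.random((20, 20))
        cost = _gradient_cost(img)
        h, w = cost.shape
        rows, cols, vals = [], [], []
        for r0 in range(h):
            for c0 in range(w):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        r1, c1 = r0 + dr, c0 + dc
                        if 0 <= r1 < h and 0 <= c1 < w:
                            rows.append(r0 * w + c0)
                            cols.append(r1 * w + c1)
                            vals.append(cost[r1, c1] * (np.sqrt(2) if dr and dc else 1))
        graph = sp.csr_matrix((vals, (rows, cols)), shape=(h * w, h * w))
        dist = dijkstra(graph, indices=[2 * w + 3])[0]
        _, mine = _dijkstra_path(cost, (2, 3), (17, 15))
        assert mine == pytest.approx(dist[17 * w + 15], abs=1e-9)

    def test_seed_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            livewire_contour(np.ones((10, 10)), [(0, 0), (5, 5), (20, 3)])

    def test_fewer_than_three_seeds_rejected(self):
        with pytest.raises(ValueError, match="3 seed"):
            livewire_contour(np.ones((10, 10)), [(0, 0), (5, 5)])

    def test_contour_normalized_counterclockwise(self):
        import shapely

        pts = np.array([[0, 0], [0, 4], [4, 4], [4, 0]], float)  # clockwise
        c = SliceContour(pts, 0)
        assert shapely.LinearRing(c.points).is_ccw


class TestSignalInclusion:
    @staticmethod
    def labels_with_blob(touching):
        data = np.zeros((20, 20, 20), np.uint8)
        data[2:18, 2:18, 2:18] = HYPOINTENSE
        if touching:
            data[8:12, 8:12, 14:19] = HYPERINTENSE  # reaches the surface at 17/18
        else:
            data[8:12, 8:12, 8:12] = HYPERINTENSE
        return LabelVolume(data, (1, 1, 1), (0, 0, 0))

    def test_rimmed_core_lesion_included(self):
        vol = self.labels_with_blob(touching=False)
        hypo = (vol.data == HYPOINTENSE).sum()
        blob = (vol.data == HYPERINTENSE).sum()
        out = apply_signal_inclusion(vol)
        assert out.data.sum() == hypo + blob

    def test_surface_contacting_lesion_excluded(self):
        vol = self.labels_with_blob(touching=True)
        hypo = (vol.data == HYPOINTENSE).sum()
        out = apply_signal_inclusion(vol)
        assert out.data.sum() == hypo
        # concavity: the split voxels are background in the final mask
        assert not out.data[9, 9, 15]

    def test_no_hyperintense_is_identity(self):
        data = np.zeros((8, 8, 8), np.uint8)
        data[2:6, 2:6, 2:6] = HYPOINTENSE
        vol = LabelVolume(data, (1, 1, 1))
        out = apply_signal_inclusion(vol)
        assert np.array_equal(out.data, data == HYPOINTENSE)


def stack_of_circles(radii, slice_spacing=3.6, spacing=0.2, h=80, w=80):
    masks = np.stack([circle_mask(h, w, r, spacing=spacing) for r in radii])
    return PlanarStack("axial", masks, (spacing, spacing), slice_spacing)


class TestInterpolation:
    def test_identical_circles_give_cylinder(self):
        """Two identical r=5 circles 3.6 mm apart enclose pi*r^2*h."""
        stack = stack_of_circles([5.0, 5.0])
        vol = interpolate_stack(stack, 0.2)
        assert vol.occupied_volume_mm3() == pytest.approx(np.pi * 25 * 3.6, rel=0.05)

    def test_frustum_volume(self):
        """Radii 5 and 3 on adjacent slices give the conical frustum."""
        stack = stack_of_circles([5.0, 3.0])
        vol = interpolate_stack(stack, 0.2)
        expected = (np.pi * 3.6 / 3) * (25 + 15 + 9)
        assert vol.occupied_volume_mm3() == pytest.approx(expected, rel=0.05)

    def test_single_slice_extrudes_one_slice_thickness(self):
        stack = stack_of_circles([4.0])
        vol = interpolate_stack(stack, 0.2)
        assert vol.extent_mm[2] == pytest.approx(3.6, abs=0.2)
        assert vol.occupied_volume_mm3() == pytest.approx(np.pi * 16 * 3.6, rel=0.05)

    def test_monotone_in_contour_nesting(self):
        """A stack of larger contours yields a superset solid."""
        small = interpolate_stack(stack_of_circles([3.0, 2.0, 3.0]), 0.3)
        big = interpolate_stack(stack_of_circles([5.0, 4.0, 5.0]), 0.3)
        assert big.data[small.data].all()

    def test_nonpositive_target_spacing_rejected(self):
        with pytest.raises(ValueError):
            interpolate_stack(stack_of_circles([5.0, 5.0]), 0.0)


class TestSurfaceExtraction:
    def test_voxel_cube_volume(self):
        occ = np.zeros((14, 14, 14), bool)
        occ[2:12, 2:12, 2:12] = True  # 10 mm cube at 1 mm spacing
        mesh = extract_surface(LabelVolume(occ, (1, 1, 1)))
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(1000.0, rel=0.05)

    def test_sphere_volume_at_half_mm(self):
        sp = 0.5
        n = 48
        xs = (np.arange(n) + 0.5) * sp - 12
        gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
        occ = gx**2 + gy**2 + gz**2 <= 100.0
        mesh = extract_surface(LabelVolume(occ, np.full(3, sp)))
        assert mesh.volume == pytest.approx(4188.79, rel=0.02)

    def test_two_blobs_give_two_watertight_components(self):
        occ = np.zeros((30, 12, 12), bool)
        occ[2:10, 2:10, 2:10] = True
        occ[18:28, 2:10, 2:10] = True
        mesh = extract_surface(LabelVolume(occ, (1, 1, 1)))
        parts = mesh.split(only_watertight=False)
        assert len(parts) == 2
        assert all(p.is_watertight for p in parts)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(LabelVolume(np.zeros((5, 5, 5), bool), (1, 1, 1)))

    def test_rasterize_round_trip_preserves_volume(self, coarse_phantom):
        """extract_surface then voxel parity fill recovers the solid."""
        from ddft3d._mesh import rasterize_mesh

        vol = coarse_phantom.occupancy
        mesh = extract_surface(vol)
        back = rasterize_mesh(mesh, vol.origin, vol.spacing, vol.shape)
        assert back.occupied_volume_mm3() == pytest.approx(
            vol.occupied_volume_mm3(), rel=0.05
        )
        assert vol.dice(back) > 0.97
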