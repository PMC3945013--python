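"""Geometry: synthetic atrium, voxel shell, fibers, electrode placement."""

import numpy as np
import pytest

from atriamap import geometry as geo
from atriamap.kernels import winding_number


class TestSyntheticAtrium:
    def test_sphere_mode_is_closed_with_euler_characteristic_2(self):
        s = geo.make_synthetic_atrium(holes=None, appendage_amp=0.0,
                                      jitter=0.0)
        assert s.closed
        assert s.boundary_loops() == []
        v = s.n_nodes
        f = len(s.triangles)
        e = 3 * f // 2
        assert v - e + f == 2

    def test_default_atrium_has_three_boundary_loops(self, atrium):
        loops = atrium.boundary_loops()
        assert len(loops) == 3
        # rims are labeled and form the boundary loops
        rim_nodes = set()
        for tag in ("SVC-rim", "IVC-rim", "valve-rim"):
            idx = atrium.label_of(tag)
            assert idx.size > 0
            rim_nodes.update(idx.tolist())
        assert rim_nodes == {int(i) for loop in loops for i in loop}

    def test_same_seed_reproduces_identical_nodes(self):
        a = geo.make_synthetic_atrium(seed=7)
        b = geo.make_synthetic_atrium(seed=7)
        np.testing.assert_array_equal(a.nodes, b.nodes)

    def test_different_seed_changes_surface(self):
        a = geo.make_synthetic_atrium(seed=7)
        b = geo.make_synthetic_atrium(seed=8)
        assert not np.allclose(a.nodes, b.nodes)

    def test_close_holes_yields_watertight_surface(self, atrium):
        closed = geo.close_holes(atrium)
        assert closed.closed
        closed.check_edge_manifold()
        # winding number certifies consistent outward orientation
        w = winding_number(closed.nodes, closed.triangles,
                           closed.nodes.mean(axis=0))
        assert w[0] == pytest.approx(1.0, abs=1e-9)

    def test_label_roundtrip_through_ply(self, atrium, tmp_path):
        path = tmp_path / "atrium.ply"
        atrium.save(path)
        back = geo.TriSurface.load(path)
        assert set(back.labels) == set(atrium.labels)
        np.testing.assert_array_equal(back.label_of("SVC-rim"),
                                      atrium.label_of("SVC-rim"))
        np.testing.assert_allclose(back.nodes, atrium.nodes, atol=1e-4)


class TestVoxelShell:
    def test_plane_patch_has_seven_layers_at_default_resolution(self):
        # flat patch at z=0: 1.75 mm wall at 0.25 mm yields 7 voxel layers
        n = 12
        xs, ys = np.meshgrid(np.arange(n), np.arange(n))
        nodes = np.column_stack([xs.ravel() * 2.0, ys.ravel() * 2.0,
                                 np.zeros(n * n)])
        tris = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                tris.append([a, a + 1, a + n])
                tris.append([a + 1, a + n + 1, a + n])
        surf = geo.TriSurface(nodes, np.asarray(tris), closed=False)
        lat = geo.voxelize_shell(surf, thickness=1.75, h=0.25,
                                 keep_largest=False)
        # one voxel column over the patch interior
        col = lat.centers[
            (np.abs(lat.centers[:, 0] - 11.125) < 0.01)
            & (np.abs(lat.centers[:, 1] - 11.125) < 0.01)
        ]
        assert len(col) == 7
        np.testing.assert_allclose(sorted(col[:, 2]),
                                   0.125 + 0.25 * np.arange(7))

    def test_spherical_shell_volume_matches_analytic(self, sphere_surface):
        lat = geo.voxelize_shell(sphere_surface, thickness=1.75, h=0.5)
        vol = lat.n_voxels * lat.h ** 3
        r = 20.0
        t = 1.75
        analytic = 4.0 / 3.0 * np.pi * ((r + t) ** 3 - r ** 3)
        assert vol == pytest.approx(analytic, rel=0.15)

    def test_halving_h_scales_voxel_count_by_8(self, sphere_surface):
        lat1 = geo.voxelize_shell(sphere_surface, thickness=1.75, h=1.0 / 2)
        lat2 = geo.voxelize_shell(sphere_surface, thickness=1.75, h=1.0 / 4)
        assert lat2.n_voxels / lat1.n_voxels == pytest.approx(8.0, rel=0.10)

    def test_volume_estimate_converges_under_refinement(self, atrium):
        lat1 = geo.voxelize_shell(atrium, thickness=1.75, h=0.7)
        lat2 = geo.voxelize_shell(atrium, thickness=1.75, h=0.35)
        v1 = lat1.n_voxels * lat1.h ** 3
        v2 = lat2.n_voxels * lat2.h ** 3
        assert abs(v1 - v2) / v2 < 0.05

    def test_unresolvable_wall_is_refused(self, sphere_surface):
        with pytest.raises(ValueError, match="unresolvable"):
            geo.voxelize_shell(sphere_surface, thickness=0.4, h=0.25)

    def test_lattice_is_single_connected_component(self, atrium):
        from scipy import ndimage

        lat = geo.voxelize_shell(atrium, thickness=1.75, h=0.5)
        dense = lat.index_grid >= 0
        _, n = ndimage.label(dense)
        assert n == 1


class TestFibers:
    def test_unit_norm_and_wall_tangency(self, sphere_surface):
        lat = geo.voxelize_shell(sphere_surface, thickness=1.75, h=0.5)
        fib = geo.assign_fibers(lat)
        norms = np.linalg.norm(fib.vectors, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)
        normal_comp = np.abs(np.einsum("ij,ij->i", fib.vectors, lat.normal))
        assert normal_comp.mean() < 0.2

    def test_circumferential_rule_follows_latitude_circles(
            self, sphere_surface):
        lat = geo.voxelize_shell(sphere_surface, thickness=1.75, h=0.5)
        fib = geo.assign_fibers(lat, axis=(0, 0, 1))
        c = lat.centers - lat.centers.mean(axis=0)
        # away from the poles, fibers must be orthogonal to both z and the
        # radial direction
        mask = np.abs(c[:, 2]) < 10.0
        assert np.abs(fib.vectors[mask, 2]).max() < 0.3
        radial = c[mask] / np.linalg.norm(c[mask], axis=1, keepdims=True)
        dots = np.abs(np.einsum("ij,ij->i", fib.vectors[mask], radial))
        assert dots.mean() < 0.1


class TestElectrodeArrays:
    def test_flat_surface_control_points_give_exact_grid(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([0.0, 5.0, 0.0])   # first row, 6 columns -> unit steps
        c = np.array([2.0, 3.0, 0.0])   # grid-center slot (2,3), unit spacing
        arr = geo.place_plaques(
            None, [[a, b, c]], plaque_shapes=[(4, 6)], omit=[[]],
            project=False,
        )
        assert arr.n_channels == 24
        ii, jj = np.meshgrid(np.arange(4), np.arange(6), indexing="ij")
        expected = np.column_stack([ii.ravel(), jj.ravel(),
                                    np.zeros(24)]).astype(float)
        np.testing.assert_allclose(arr.positions, expected, atol=1e-9)

    def test_default_layout_has_103_distinct_channels_near_surface(
            self, atrium):
        cps = geo.default_plaque_control_points(atrium)
        sampler = geo.SurfaceSampler(atrium, spacing=0.5)
        arr = geo.place_plaques(atrium, cps, sampler=sampler)
        assert arr.n_channels == 103
        assert len(np.unique(np.round(arr.positions, 6), axis=0)) == 103
        d, _, _, _ = sampler.nearest(arr.positions)
        # electrodes sit on the epicardium: one wall thickness away
        np.testing.assert_allclose(d, 1.75, atol=0.5)

    def test_collinear_control_points_are_refused(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([0.0, 5.0, 0.0])
        c = np.array([0.0, 2.5, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            geo.place_plaques(None, [[a, b, c]], plaque_shapes=[(4, 6)],
                              omit=[[]], project=False,
                              control_indices=[[(0, 0), (0, 5), (0, 2)]])


class TestBalloon:
    def test_64_interior_electrodes_with_expected_clearance(
            self, sphere_surface):
        bal = geo.place_balloon(sphere_surface, center=(0, 0, 0),
                                radius=10.0)
        assert bal.positions.shape == (64, 3)
        r = np.linalg.norm(bal.positions, axis=1)
        assert r.max() < 20.0
        # sphere R=20 with balloon z-semi-axis 12.5: clearance >= 7.5
        assert (20.0 - r).min() == pytest.approx(7.5, abs=0.5)

    def test_interior_test_agrees_with_winding_number_oracle(
            self, sphere_surface):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-25, 25, size=(200, 3))
        inside_oracle = winding_number(
            sphere_surface.nodes, sphere_surface.triangles, pts) > 0.5
        inside_radius = np.linalg.norm(pts, axis=1) < 20.0
        # the analytic radius check and the solid-angle winding number must
        # agree except within a band near the faceted surface
        band = np.abs(np.linalg.norm(pts, axis=1) - 20.0) > 0.5
        assert np.array_equal(inside_oracle[band], inside_radius[band])

    def test_oversized_balloon_is_refused(self, sphere_surface):
        with pytest.raises(ValueError, match="outside"):
            geo.place_balloon(sphere_surface, center=(0, 0, 0), radius=25.0)
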