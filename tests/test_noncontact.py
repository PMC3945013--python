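"""Boundary-element operators and Tikhonov inverse."""

import numpy as np
import pytest

from atriamap import geometry as geo
from atriamap import noncontact as nc
from atriamap.electrogram import EgmSet


@pytest.fixture(scope="module")
def sphere_forward(sphere_surface):
    bal = geo.place_balloon(sphere_surface, center=(0, 0, 0), radius=8.0)
    return nc.assemble_forward(sphere_surface, bal), bal


def _exterior_source_field(surface, points, src):
    return (1.0 / np.linalg.norm(surface.nodes - src, axis=1),
            1.0 / np.linalg.norm(points - src, axis=1))


class TestSolidAngle:
    def test_interior_point_closes_to_4pi(self, sphere_surface):
        w = nc.solid_angle_row(sphere_surface, [3.0, -2.0, 5.0])
        assert w.sum() == pytest.approx(4 * np.pi, abs=1e-9)

    def test_exterior_point_closes_to_zero(self, sphere_surface):
        w = nc.solid_angle_row(sphere_surface, [30.0, 0.0, 0.0])
        assert w.sum() == pytest.approx(0.0, abs=1e-9)

    def test_tetrahedron_centroid_sees_pi_per_face(self):
        nodes = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float)
        tris = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        surf = geo.TriSurface(nodes, tris)
        from atriamap.kernels import triangle_solid_angles

        omega = triangle_solid_angles(nodes, tris.astype(np.int64),
                                      np.zeros(3))
        np.testing.assert_allclose(omega, np.pi, atol=1e-12)


class TestSingleLayer:
    def test_far_field_weight_sum_is_area_over_distance(self):
        tri = geo.TriSurface(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            np.array([[0, 1, 2]]), closed=False,
        )
        d = 100.0
        w = nc.single_layer_row(tri, [1 / 3, 1 / 3, d])
        assert w.sum() == pytest.approx(0.5 / d, rel=1e-2)

    def test_matches_quadrature_oracle_near_field(self):
        tri_nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        tri = geo.TriSurface(tri_nodes, np.array([[0, 1, 2]]), closed=False)
        x = np.array([0.3, 0.2, 0.15])
        # midpoint quadrature over a fine barycentric subdivision
        n = 600
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        lower = (i + j) < n
        a = (i[lower] + 1 / 3) / n
        b = (j[lower] + 1 / 3) / n
        pts = np.column_stack([a, b, np.zeros(a.size)])
        upper = (i + j) < n - 1
        a2 = (i[upper] + 2 / 3) / n
        b2 = (j[upper] + 2 / 3) / n
        pts2 = np.column_stack([a2, b2, np.zeros(a2.size)])
        cell = 0.5 / (n * n)
        oracle = cell * (
            (1 / np.linalg.norm(pts - x, axis=1)).sum()
            + (1 / np.linalg.norm(pts2 - x, axis=1)).sum()
        )
        w = nc.single_layer_row(tri, x)
        assert w.sum() == pytest.approx(oracle, rel=1e-4)

    def test_singular_evaluation_on_triangle_is_finite(self):
        tri = geo.TriSurface(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            np.array([[0, 1, 2]]), closed=False,
        )
        w = nc.single_layer_row(tri, [1 / 3, 1 / 3, 0.0])
        assert np.all(np.isfinite(w))
        assert w.sum() > 0

    def test_weights_scale_inversely_with_distance(self):
        tri = geo.TriSurface(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            np.array([[0, 1, 2]]), closed=False,
        )
        w1 = nc.single_layer_row(tri, [0, 0, 50.0]).sum()
        w2 = nc.single_layer_row(tri, [0, 0, 100.0]).sum()
        assert w1 / w2 == pytest.approx(2.0, rel=1e-3)


class TestForwardMatrix:
    def test_double_layer_rows_sum_to_one(self, sphere_forward):
        tm, _ = sphere_forward
        np.testing.assert_allclose(tm.s_ee.sum(axis=1), 1.0, atol=1e-9)

    def test_constant_potential_reproduction(self, sphere_forward):
        tm, _ = sphere_forward
        np.testing.assert_allclose(tm.t_ec @ np.ones(tm.n_nodes), 1.0,
                                   atol=1e-6)

    def test_green_identity_oracle_under_2pct(self, sphere_surface,
                                              sphere_forward):
        tm, bal = sphere_forward
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(20):
            d = rng.normal(size=3)
            src = 21.0 * d / np.linalg.norm(d)   # inside the wall
            phi_e, phi_c = _exterior_source_field(sphere_surface,
                                                  bal.positions, src)
            pred = tm.t_ec @ phi_e
            errs.append(np.linalg.norm(pred - phi_c)
                        / np.linalg.norm(phi_c))
        assert max(errs) < 0.02

    def test_forward_error_decreases_with_refinement(
            self, coarse_sphere_surface, sphere_surface):
        import trimesh

        fine = trimesh.creation.icosphere(4, radius=20.0)
        fine_surface = geo.TriSurface(np.asarray(fine.vertices),
                                      np.asarray(fine.faces, dtype=np.int64))
        rng = np.random.default_rng(1)
        errors = []
        for surf in (coarse_sphere_surface, sphere_surface, fine_surface):
            bal = geo.place_balloon(surf, center=(0, 0, 0), radius=8.0)
            tm = nc.assemble_forward(surf, bal)
            errs = []
            for _ in range(10):
                d = rng.normal(size=3)
                src = 21.0 * d / np.linalg.norm(d)
                phi_e, phi_c = _exterior_source_field(surf, bal.positions,
                                                      src)
                errs.append(np.linalg.norm(tm.t_ec @ phi_e - phi_c)
                            / np.linalg.norm(phi_c))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]
        assert errors[0] < 0.10  # even N=162 is below the coarse bound

    def test_open_surface_is_refused(self, atrium):
        bal_dummy = geo.place_balloon(atrium)
        with pytest.raises(ValueError, match="closed"):
            nc.assemble_forward(atrium, bal_dummy)


class TestTikhonov:
    def test_orthonormal_matrix_at_lambda_zero_gives_transpose(self):
        rng = np.random.default_rng(2)
        q = np.linalg.qr(rng.normal(size=(64, 64)))[0]
        np.testing.assert_allclose(nc.tikhonov_inverse(q, 0.0), q.T,
                                   atol=1e-12)

    def test_norm_vanishes_monotonically_as_lambda_grows(self,
                                                         sphere_forward):
        tm, _ = sphere_forward
        lams = [1e-8, 1e-6, 1e-4, 1e-2, 1.0, 100.0]
        norms = [np.linalg.norm(nc.tikhonov_inverse(tm.t_ec, l), 2)
                 for l in lams]
        # non-increasing (flat in the unregularized plateau, then shrinking)
        assert all(a >= b * (1.0 - 1e-9)
                   for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_negative_lambda_is_refused(self, sphere_forward):
        tm, _ = sphere_forward
        with pytest.raises(ValueError):
            nc.tikhonov_inverse(tm.t_ec, -1e-5)

    def test_low_frequency_field_roundtrip(self, sphere_surface,
                                           sphere_forward):
        tm, _ = sphere_forward
        phi = sphere_surface.nodes[:, 2] / 20.0   # dipolar surface pattern
        rec = nc.tikhonov_inverse(tm.t_ec, 1e-6) @ (tm.t_ec @ phi)
        assert np.corrcoef(rec, phi)[0, 1] > 0.9


class TestReconstruction:
    def test_zero_in_zero_out_and_linearity(self, sphere_forward):
        tm, bal = sphere_forward
        t_ce = nc.tikhonov_inverse(tm.t_ec, 1e-6)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(64, 30))
        y = rng.normal(size=(64, 30))
        ex = EgmSet(bal.positions, x)
        ey = EgmSet(bal.positions, y)
        exy = EgmSet(bal.positions, 2.0 * x - 3.0 * y)
        assert np.all(nc.reconstruct(
            EgmSet(bal.positions, np.zeros((64, 10))), t_ce).waveforms == 0)
        np.testing.assert_allclose(
            nc.reconstruct(exy, t_ce).waveforms,
            2.0 * nc.reconstruct(ex, t_ce).waveforms
            - 3.0 * nc.reconstruct(ey, t_ce).waveforms, atol=1e-9)

    def test_channel_mismatch_is_refused(self, sphere_forward):
        tm, bal = sphere_forward
        t_ce = nc.tikhonov_inverse(tm.t_ec, 1e-6)
        bad = EgmSet(bal.positions[:32], np.zeros((32, 5)))
        with pytest.raises(ValueError, match="channels"):
            nc.reconstruct(bad, t_ce)


class TestLambdaCalibration:
    def test_single_value_grid_returns_it(self, sphere_forward):
        tm, bal = sphere_forward
        direct = EgmSet(tm.surface.nodes, np.zeros((tm.n_nodes, 5)))
        cat = EgmSet(bal.positions, np.zeros((64, 5)))
        lam, errors = nc.calibrate_lambda(direct, cat, tm.t_ec,
                                          np.array([3e-4]))
        assert lam == 3e-4
        assert len(errors) == 1

    def test_every_grid_point_evaluated_and_argmin_returned(
            self, sphere_surface, sphere_forward):
        tm, bal = sphere_forward
        rng = np.random.default_rng(4)
        src = np.array([0.0, 0.0, 21.0])
        phi_e, phi_c = _exterior_source_field(sphere_surface, bal.positions,
                                              src)
        t = np.linspace(0, 1, 8)
        direct = EgmSet(sphere_surface.nodes, np.outer(phi_e, t))
        cat = EgmSet(bal.positions,
                     np.outer(phi_c, t) + 1e-4 * rng.normal(size=(64, 8)))
        grid = np.logspace(-9, -1, 9)
        lam, errors = nc.calibrate_lambda(direct, cat, tm.t_ec, grid)
        assert len(errors) == len(grid)
        assert lam == grid[np.argmin(errors)]

    def test_empty_grid_is_refused(self, sphere_forward):
        tm, bal = sphere_forward
        direct = EgmSet(tm.surface.nodes, np.zeros((tm.n_nodes, 5)))
        cat = EgmSet(bal.positions, np.zeros((64, 5)))
        with pytest.raises(ValueError, match="empty"):
            nc.calibrate_lambda(direct, cat, tm.t_ec, np.array([]))
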