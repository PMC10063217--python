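"""Stokes-flow kernel, head mesh and boundary-integral operator tests."""

import numpy as np
import pytest
from scipy.integrate import quad

from archswim.hydrodynamics import (
    reg_stokeslet,
    blob,
    build_head_mesh,
    stokeslet_matrix,
    assemble_velocity_operator,
    rigid_body_velocity,
    repulsive_force,
    pose_points,
)


class TestKernel:
    def test_self_interaction(self):
        eps = 0.07
        S = reg_stokeslet([1.0, -2.0, 0.5], [1.0, -2.0, 0.5], eps)
        np.testing.assert_allclose(S, np.eye(3) / (4 * np.pi * eps), rtol=1e-13)

    def test_symmetry_and_translation(self, rng):
        x, y, c = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
        S = reg_stokeslet(x, y, 0.05)
        np.testing.assert_allclose(S, S.T, atol=1e-15)
        np.testing.assert_allclose(S, reg_stokeslet(x + c, y + c, 0.05), rtol=1e-12)

    def test_far_field_matches_singular_stokeslet(self):
        eps = 0.01
        x, y = np.array([1.0, 0.3, -0.2]), np.array([0.0, 0.0, 0.0])
        r = x - y
        d = np.linalg.norm(r)
        x = y + r * (100 * eps / d)       # |r| = 100 eps
        r = x - y
        d = np.linalg.norm(r)
        exact = (np.eye(3) / d + np.outer(r, r) / d**3) / (8 * np.pi)
        S = reg_stokeslet(x, y, eps)
        assert np.max(np.abs(S - exact)) / np.max(np.abs(exact)) < 1e-3

    def test_matrix_agrees_with_single_pairs(self, rng):
        t, s = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        K = stokeslet_matrix(t, s, 0.1)
        for i in (0, 3):
            for j in (1, 4):
                np.testing.assert_allclose(K[i, :, j, :],
                                           reg_stokeslet(t[i], s[j], 0.1), rtol=1e-13)

    def test_positive_definite_on_separated_sets(self, rng):
        pts = rng.uniform(0, 5, size=(12, 3))
        K = stokeslet_matrix(pts, pts, 0.05).reshape(36, 36)
        K = 0.5 * (K + K.T)
        assert np.linalg.eigvalsh(K).min() > 0


class TestBlob:
    def test_peak_value(self):
        eps = 0.2
        assert blob([0, 0, 0], eps) == pytest.approx(15 / (8 * np.pi * eps**3))

    def test_radial_symmetry(self, rng):
        v = rng.normal(size=3)
        v1 = 0.37 * v / np.linalg.norm(v)
        v2 = 0.37 * np.array([1.0, 0, 0])
        assert blob(v1, 0.1) == pytest.approx(blob(v2, 0.1), rel=1e-12)

    def test_integrates_to_one(self):
        eps = 0.05
        f = lambda r: 4 * np.pi * r**2 * blob([r, 0, 0], eps)
        inner, _ = quad(f, 0, 50 * eps)
        assert inner == pytest.approx(1.0, rel=0.01)


class TestHeadMesh:
    def test_sphere_surface_area(self):
        mesh = build_head_mesh((1.0, 1.0, 1.0), target_Q=16, refinement=4)
        assert mesh.fine_weights.sum() == pytest.approx(4 * np.pi, rel=0.01)

    def test_points_on_ellipsoid(self):
        ax = np.array([0.04, 0.032, 0.02])
        mesh = build_head_mesh(ax, 16, 4)
        for pts in (mesh.coarse, mesh.fine):
            resid = np.sum((pts / ax) ** 2, axis=1) - 1.0
            assert np.max(np.abs(resid)) < 1e-12

    def test_mirror_symmetry(self):
        mesh = build_head_mesh((0.04, 0.032, 0.02), 16, 4)
        for pts in (mesh.coarse, mesh.fine):
            mirrored = pts * np.array([1, 1, -1])
            d = np.min(np.linalg.norm(pts[:, None] - mirrored[None], axis=2), axis=0)
            assert np.max(d) < 1e-12
        assert not np.any(np.isclose(mesh.fine[:, 2], 0.0))

    def test_nearest_map_properties(self):
        mesh = build_head_mesh((0.04, 0.032, 0.02), 12, 3)
        assert mesh.nn.shape == (mesh.Qf,)
        assert np.all((mesh.nn >= 0) & (mesh.nn < mesh.Q))
        counts = np.bincount(mesh.nn, minlength=mesh.Q)
        assert np.all(counts >= 1)
        # map is the true nearest neighbor (allowing the orphan-rescue ties)
        d2 = np.sum((mesh.fine[:, None] - mesh.coarse[None]) ** 2, axis=2)
        frac_exact = np.mean(mesh.nn == np.argmin(d2, axis=1))
        assert frac_exact > 0.9

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            build_head_mesh((1.0, 0.0, 1.0), 16, 4)
        with pytest.raises(ValueError):
            build_head_mesh((1, 1, 1), 4, 4)


class TestRigidBody:
    def test_pure_translation(self):
        Y = np.array([[0.1, 0.2, 0.05], [0.0, -0.1, -0.05]])
        v = rigid_body_velocity(np.array([1.0, 2.0]), 0.0, Y, np.zeros(2))
        np.testing.assert_allclose(v[:, 0], 1.0)
        np.testing.assert_allclose(v[:, 1], 2.0)
        np.testing.assert_allclose(v[:, 2], 0.0)

    def test_pure_rotation(self):
        Y = np.array([0.3, 0.0, 0.0])
        v = rigid_body_velocity(np.zeros(2), 2.0, Y, np.zeros(2))
        np.testing.assert_allclose(v, [0.0, 0.6, 0.0], atol=1e-15)

    def test_rotation_speed_scales_with_radius(self, rng):
        X0 = rng.normal(size=2)
        omega = 1.3
        Y = np.column_stack([rng.normal(size=6, scale=0.1) + X0[0],
                             rng.normal(size=6, scale=0.1) + X0[1],
                             np.zeros(6)])
        v = rigid_body_velocity(np.zeros(2), omega, Y, X0)
        radii = np.hypot(Y[:, 0] - X0[0], Y[:, 1] - X0[1])
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), omega * radii, rtol=1e-12)


def sphere_drag(a=1.0, Q=32, refinement=4, eps=0.02):
    """Solve the discrete head-only mobility problem for unit x-translation."""
    mesh = build_head_mesh((a, a, a), Q, refinement)
    op = assemble_velocity_operator(np.zeros((0, 2)), mesh, np.zeros(2), 0.0,
                                    eps, 1.0)
    U = np.zeros(3 * mesh.Q)
    U[0::3] = 1.0
    phi = np.linalg.solve(op.G_hh, U)
    return float(mesh.coarse_weights @ phi[0::3])


class TestSphereDrag:
    def test_drag_matches_stokes_law(self):
        drag = sphere_drag()
        assert drag == pytest.approx(6 * np.pi, rel=0.02)

    def test_refinement_improves(self):
        errs = [abs(sphere_drag(Q=q, refinement=4, eps=0.02) - 6 * np.pi)
                for q in (12, 24, 32)]
        assert errs[2] < errs[1] < errs[0]


class TestNearestEquivalence:
    def test_matches_direct_fine_assembly(self, rng):
        """NEAREST equals brute-force fine-grid assembly with piecewise-
        constant traction per coarse cell, by construction."""
        mesh = build_head_mesh((0.04, 0.032, 0.02), 12, 3)
        X0 = np.array([0.3, -0.2])
        phi_head = 0.4
        mid = rng.uniform(0, 1, size=(6, 2))
        eps = 0.01
        op = assemble_velocity_operator(mid, mesh, X0, phi_head, eps, 1.0 / 6)
        phi = rng.normal(size=(mesh.Q, 3))
        # brute force: loop over fine nodes, traction of the mapped coarse node
        fine = pose_points(mesh.fine, X0, phi_head, mesh.junction)
        coarse = pose_points(mesh.coarse, X0, phi_head, mesh.junction)
        mid3 = np.hstack([mid, np.zeros((6, 1))])
        v_flag = np.zeros((6, 3))
        v_head = np.zeros((mesh.Q, 3))
        from archswim.hydrodynamics import reg_stokeslet
        for p in range(mesh.Qf):
            Sf = mesh.fine_weights[p] * phi[mesh.nn[p]]
            for t in range(6):
                v_flag[t] += reg_stokeslet(mid3[t], fine[p], eps) @ Sf
            for q in range(mesh.Q):
                v_head[q] += reg_stokeslet(coarse[q], fine[p], eps) @ Sf
        np.testing.assert_allclose(
            op.flagellum_velocity(np.zeros((6, 2)), phi), v_flag[:, :2], atol=1e-12)
        np.testing.assert_allclose(
            op.head_velocity(np.zeros((6, 2)), phi), v_head, atol=1e-12)

    def test_single_stokeslet_quadrature(self):
        """One segment with unit force: velocity = weight * kernel."""
        mesh = build_head_mesh((0.04, 0.032, 0.02), 12, 3)
        h = 0.25
        mid = np.array([[0.1, 0.0], [5.0, 0.0]])
        eps = 0.003
        op = assemble_velocity_operator(mid, mesh, np.array([-20.0, 0.0]), 0.0,
                                        eps, h)
        f = np.array([[1.0, 0.0], [0.0, 0.0]])
        v = op.flagellum_velocity(f, np.zeros((mesh.Q, 3)))
        S = reg_stokeslet([5.0, 0, 0], [0.1, 0, 0], eps)
        np.testing.assert_allclose(v[1], h * S[:2, 0], rtol=1e-12)

    def test_operator_linearity(self, rng):
        mesh = build_head_mesh((0.04, 0.032, 0.02), 12, 3)
        mid = rng.uniform(0, 1, size=(5, 2))
        op = assemble_velocity_operator(mid, mesh, np.zeros(2), 0.1, 0.01, 0.2)
        f = rng.normal(size=(5, 2))
        phi = rng.normal(size=(mesh.Q, 3))
        np.testing.assert_allclose(op.flagellum_velocity(2 * f, 2 * phi),
                                   2 * op.flagellum_velocity(f, phi), rtol=1e-12)


class TestRepulsion:
    def test_zero_when_separated(self):
        mid = np.column_stack([np.linspace(0.05, 0.95, 10), np.zeros(10)])
        s = np.linspace(0.05, 0.95, 10)
        fine = np.full((4, 3), 50.0)
        f = repulsive_force(mid, s, fine, np.ones(4), A=100.0, B=400.0,
                            delta_excl=0.2, cutoff=0.01, h=0.1)
        np.testing.assert_allclose(f, 0.0)

    def test_straight_isolated_filament(self):
        N = 20
        s = (np.arange(N) + 0.5) / N
        mid = np.column_stack([s, np.zeros(N)])
        fine = np.full((4, 3), 50.0)
        # only excluded-neighborhood pairs fall inside the cutoff
        f = repulsive_force(mid, s, fine, np.ones(4), A=100.0, B=160.0,
                            delta_excl=2 / N, cutoff=0.1, h=1 / N)
        np.testing.assert_allclose(f, 0.0)

    def test_pair_kernel_peak_location(self):
        B = 37.0
        d = np.linspace(1e-3, 0.5, 20000)
        mag = np.exp(-B * d) * (1 - np.exp(-B * d))
        assert d[np.argmax(mag)] == pytest.approx(np.log(2) / B, rel=1e-2)

    def test_two_close_segments_repel(self):
        mid = np.array([[0.0, 0.0], [0.01, 0.0], [0.0, 0.02], [0.01, 0.02]])
        s = np.array([0.1, 0.3, 0.6, 0.8])
        fine = np.full((1, 3), 50.0)
        f = repulsive_force(mid, s, fine, np.ones(1), A=100.0, B=100.0,
                            delta_excl=0.1, cutoff=0.1, h=0.25)
        # lower pair pushed down, upper pair pushed up
        assert f[0, 1] < 0 and f[1, 1] < 0
        assert f[2, 1] > 0 and f[3, 1] > 0
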