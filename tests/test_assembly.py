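"""Coupled-system tests: equilibria, closure, and a naive-loop oracle."""

import numpy as np
import pytest

from archswim.params import DimensionlessParameters
from archswim.filament import (FlagellumShape, reconstruct_positions,
                               elastic_energy, n_active_joints)
from archswim.hydrodynamics import reg_stokeslet, build_head_mesh
from archswim.assembly import (SwimmerState, initial_state, solve_rates,
                               assemble_system, integrate, conservation_residuals,
                               _Discretization)


def small_params(**kw):
    base = dict(S=18.0, rho=36.4, M=900.0, kappa_c=1.5, N=12, head_Q=8,
                head_refinement=2, reporting_cadence=25.0)
    base.update(kw)
    return DimensionlessParameters(**base)


class TestEquilibria:
    def test_straight_passive_is_equilibrium(self):
        p = small_params(repulsion_A=0.0)
        disc = _Discretization(p)
        st = SwimmerState(shape=FlagellumShape(theta=np.zeros(p.N)),
                          m=np.zeros(disc.n_active))
        sol = solve_rates(st, p, disc)
        assert np.abs(sol.thetadot).max() < 1e-12
        assert np.abs(sol.X0dot).max() < 1e-12
        assert np.abs(sol.f).max() < 1e-12
        assert np.abs(sol.phi).max() < 1e-12

    def test_rates_linear_in_moment(self):
        p = small_params(repulsion_A=0.0)
        disc = _Discretization(p)
        rng = np.random.default_rng(8)
        theta = 0.3 * rng.standard_normal(p.N)
        m = rng.standard_normal(disc.n_active)
        st1 = SwimmerState(shape=FlagellumShape(theta=theta), m=m)
        st2 = SwimmerState(shape=FlagellumShape(theta=theta), m=2 * m)
        s0 = solve_rates(SwimmerState(shape=FlagellumShape(theta=theta),
                                      m=np.zeros(disc.n_active)), p, disc)
        s1 = solve_rates(st1, p, disc)
        s2 = solve_rates(st2, p, disc)
        np.testing.assert_allclose(s2.thetadot - s0.thetadot,
                                   2 * (s1.thetadot - s0.thetadot),
                                   rtol=1e-8, atol=1e-10)


class TestClosure:
    def test_force_and_moment_free(self):
        """Total force and e3 moment of (f, phi, f_rep) vanish at a generic
        bent state, recomputed by independent summation."""
        p = small_params()
        disc = _Discretization(p)
        st = initial_state(p)
        st.shape.theta = st.shape.theta + 0.4 * np.sin(
            3 * np.linspace(0, 1, p.N))
        sol = solve_rates(st, p, disc)
        from archswim.hydrodynamics import pose_points
        X = reconstruct_positions(st.shape)
        Xm = 0.5 * (X[:-1] + X[1:])
        ftot = sol.f + sol.f_rep
        fine = pose_points(disc.mesh.fine, st.shape.X0, st.shape.theta[0],
                           disc.mesh.junction)
        phi_fine = sol.phi[disc.mesh.nn]
        w = disc.mesh.fine_weights
        F = p.h * ftot.sum(axis=0) + (w[:, None] * phi_fine[:, :2]).sum(axis=0)
        scale = p.h * np.abs(ftot).sum() + (w[:, None] * np.abs(phi_fine[:, :2])).sum()
        assert np.abs(F).max() / scale < 1e-10
        rel_f = Xm - X[0]
        rel_h = fine[:, :2] - X[0]
        Mz = (p.h * (rel_f[:, 0] * ftot[:, 1] - rel_f[:, 1] * ftot[:, 0]).sum()
              + (w * (rel_h[:, 0] * phi_fine[:, 1]
                      - rel_h[:, 1] * phi_fine[:, 0])).sum())
        assert abs(Mz) / scale < 1e-10


class TestInitialState:
    def test_parabola_properties(self):
        p = small_params(N=40)
        st = initial_state(p)
        # vertex tangent nearly horizontal (first segment midpoint)
        assert abs(st.shape.theta[0]) < 0.2 * p.h
        X = reconstruct_positions(st.shape)
        L = np.sum(np.linalg.norm(np.diff(X, axis=0), axis=1))
        assert L == pytest.approx(1.0, abs=1e-12)
        # tip height matches y = 0.1 x^2 at the arclength-1 endpoint
        from scipy.optimize import brentq
        arclen = lambda x: 0.5 * (x * np.sqrt(1 + (0.2 * x) ** 2)
                                  + np.arcsinh(0.2 * x) / 0.2)
        x_end = brentq(lambda x: arclen(x) - 1, 0, 2)
        assert X[-1, 1] == pytest.approx(0.1 * x_end**2, abs=2e-4)
        assert np.max(X[:, 1]) == pytest.approx(0.1 * x_end**2, abs=2e-4)
        np.testing.assert_allclose(st.m, p.m0)

    def test_moment_default_engaged(self):
        p = small_params()
        st = initial_state(p)
        assert st.m.shape == (n_active_joints(p.N, p.ell),)


class TestOracleEquivalence:
    """Hand-assembled dense system (naive loops, single-pair kernels) must
    reproduce the packaged assembly on a 6-segment filament + small head."""

    def naive_solve(self, st, p):
        N = p.N
        h = 1.0 / N
        mesh = build_head_mesh(p.head_semi_axes, p.head_Q, p.head_refinement)
        Q, Qf = mesh.Q, mesh.Qf
        na = n_active_joints(N, p.ell)
        theta, X0, m = st.shape.theta, st.shape.X0, st.m
        # geometry by explicit loops
        X = np.zeros((N + 1, 2))
        X[0] = X0
        for j in range(N):
            X[j + 1] = X[j] + h * np.array([np.cos(theta[j]), np.sin(theta[j])])
        Xm = np.array([(X[j] + X[j + 1]) / 2 for j in range(N)])
        mid3 = np.column_stack([Xm, np.zeros(N)])
        phi_head = theta[0]
        c, s_ = np.cos(phi_head), np.sin(phi_head)
        R = np.array([[c, -s_, 0], [s_, c, 0], [0, 0, 1]])
        junc = np.array([p.head_semi_axes[0], 0.0, 0.0])
        coarse = np.array([R @ (y - junc) + np.array([X0[0], X0[1], 0.0])
                           for y in mesh.coarse])
        fine = np.array([R @ (y - junc) + np.array([X0[0], X0[1], 0.0])
                         for y in mesh.fine])
        E = lambda s: (p.rho - 1) * ((s - p.d) / p.d) ** 2 + 1 if s <= p.d else 1.0
        # active moment integral at interior joints (trapezoid + tail)
        def I_m(i):
            sj = [k / N for k in range(1, na + 1)]
            if i > na:
                return 0.0
            acc = 0.0
            for k in range(i, na):
                acc += 0.5 * h * (m[k - 1] + m[k])
            acc += max(min(p.ell, 1.0) - na * h, 0.0) * m[-1]
            return acc
        nu = 2 + N + 2 * N + 3 * Q
        A = np.zeros((nu, nu))
        b = np.zeros(nu)
        o_th, o_f, o_phi = 2, 2 + N, 2 + 3 * N
        row = 0
        # moment balance at interior joints
        for i in range(1, N):
            kap = (theta[i] - theta[i - 1]) / h
            b[row] = p.M * I_m(i) - E(i / N) * kap
            for j in range(i, N):
                arm = Xm[j] - X[i]
                A[row, o_f + 2 * j] = -p.S**4 * h * arm[1]
                A[row, o_f + 2 * j + 1] = p.S**4 * h * arm[0]
            row += 1
        # flagellar no-slip at midpoints
        for j in range(N):
            for comp in range(2):
                A[row, comp] = 1.0
                for k in range(j + 1):
                    wgt = h if k < j else h / 2
                    nvec = (-np.sin(theta[k]), np.cos(theta[k]))
                    A[row, o_th + k] += wgt * nvec[comp]
                for jp in range(N):
                    S = reg_stokeslet(mid3[j], mid3[jp], p.eps)
                    A[row, o_f + 2 * jp] -= h * S[comp, 0]
                    A[row, o_f + 2 * jp + 1] -= h * S[comp, 1]
                for pp in range(Qf):
                    S = reg_stokeslet(mid3[j], fine[pp], p.eps)
                    q = mesh.nn[pp]
                    for cc in range(3):
                        A[row, o_phi + 3 * q + cc] -= mesh.fine_weights[pp] * S[comp, cc]
                row += 1
        # head no-slip at coarse nodes
        for q in range(Q):
            rel = coarse[q] - np.array([X0[0], X0[1], 0.0])
            for comp in range(3):
                if comp < 2:
                    A[row, comp] = 1.0
                A[row, o_th] += (-rel[1], rel[0], 0.0)[comp]
                for jp in range(N):
                    S = reg_stokeslet(coarse[q], mid3[jp], p.eps)
                    A[row, o_f + 2 * jp] -= h * S[comp, 0]
                    A[row, o_f + 2 * jp + 1] -= h * S[comp, 1]
                for pp in range(Qf):
                    S = reg_stokeslet(coarse[q], fine[pp], p.eps)
                    qq = mesh.nn[pp]
                    for cc in range(3):
                        A[row, o_phi + 3 * qq + cc] -= mesh.fine_weights[pp] * S[comp, cc]
                row += 1
        # closure
        for comp in range(2):
            for j in range(N):
                A[row, o_f + 2 * j + comp] = h
            for pp in range(Qf):
                A[row, o_phi + 3 * mesh.nn[pp] + comp] += mesh.fine_weights[pp]
            row += 1
        for j in range(N):
            rel = Xm[j] - X0
            A[row, o_f + 2 * j] = -h * rel[1]
            A[row, o_f + 2 * j + 1] = h * rel[0]
        for pp in range(Qf):
            rel = fine[pp][:2] - X0
            q = mesh.nn[pp]
            A[row, o_phi + 3 * q] += -mesh.fine_weights[pp] * rel[1]
            A[row, o_phi + 3 * q + 1] += mesh.fine_weights[pp] * rel[0]
        row += 1
        assert row == nu
        u = np.linalg.solve(A, b)
        return u

    def test_solved_rates_match(self):
        p = small_params(N=6, head_Q=12, head_refinement=2, repulsion_A=0.0)
        disc = _Discretization(p)
        rng = np.random.default_rng(4)
        theta = 0.5 * rng.standard_normal(p.N)
        m = rng.uniform(-1, 1, disc.n_active)
        st = SwimmerState(shape=FlagellumShape(theta=theta,
                                               X0=np.array([0.2, -0.1])), m=m)
        u_naive = self.naive_solve(st, p)
        sol = solve_rates(st, p, disc)
        np.testing.assert_allclose(sol.X0dot, u_naive[:2], rtol=0, atol=1e-10 * (1 + np.abs(u_naive[:2]).max()))
        scale = np.abs(u_naive[2:2 + p.N]).max()
        np.testing.assert_allclose(sol.thetadot, u_naive[2:2 + p.N],
                                   rtol=0, atol=1e-10 * scale)
        fscale = np.abs(u_naive[2 + p.N:2 + 3 * p.N]).max()
        np.testing.assert_allclose(sol.f.reshape(-1),
                                   u_naive[2 + p.N:2 + 3 * p.N],
                                   rtol=0, atol=1e-10 * fscale)


class TestDynamics:
    def test_passive_relaxation_decreases_energy(self):
        p = small_params(M=0.0, max_time=40.0)
        disc = _Discretization(p)
        sm = (np.arange(p.N) + 0.5) / p.N
        st = SwimmerState(shape=FlagellumShape(theta=0.6 * np.sin(np.pi * sm)),
                          m=np.ones(disc.n_active))
        rec = integrate(st, p, 40.0, disc=disc)
        E = np.array([elastic_energy(rec.state_at(i).shape, p.rho, p.d)
                      for i in range(0, len(rec.times), 20)])
        # proximal stiff modes relax slowly (rate ~ E k^4 / S^4); by t = 40
        # the energy has dropped by orders of magnitude and never grows
        assert E[-1] < 0.02 * E[0]
        assert np.all(np.diff(E) < 1e-8 + 0.001 * E[:-1])

    def test_frozen_moment_does_not_beat(self):
        """With switching disabled (kappa_c unreachable) the moment stays on
        the engaged branch: the filament winds up steadily instead of
        oscillating -- no curvature wave, no beat-scale reversals."""
        p = small_params(kappa_c=1e6, max_time=40.0)
        disc = _Discretization(p)
        rec = integrate(initial_state(p), p, 40.0, disc=disc)
        np.testing.assert_allclose(rec.m[-1], 1.0, atol=1e-6)
        # the filament winds in one direction only: the proximal angle never
        # reverses (a beat requires periodic reversals of bending direction)
        sig = rec.theta[:, 0]
        backtrack = np.max(sig[1:] - np.minimum.accumulate(sig)[1:])
        assert backtrack < 0.01 * np.ptp(sig)
        # and the engaged moment keeps mid-flagellum curvature one-signed
        k = rec.curvature()
        mid = k[rec.times > 10.0, 3:8]
        assert np.all(mid > 0.0)

    def test_conservation_along_trajectory(self):
        p = small_params(max_time=20.0)
        disc = _Discretization(p)
        rec = integrate(initial_state(p), p, 10.0, disc=disc)
        res = conservation_residuals(rec, stride=50, disc=disc)
        assert res.max() < 1e-8
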