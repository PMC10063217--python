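"""Coupled swimmer: moment law + elastica + hydrodynamics, and time stepping.

At each instant the massless swimmer satisfies a square linear system in
the unknowns (Xdot0, thetadot for the N segments, force density f on the N
flagellar segments, traction phi on the Q coarse head nodes):

* the elastohydrodynamic moment balance collocated at the N-1 interior
  joints (algebraic in f, the shape being known);
* the no-slip condition on the flagellum at segment midpoints (in-plane):
  the exact kinematic velocity of the chain equals the boundary-integral
  velocity induced by (f + f_rep, phi);
* the no-slip condition at the coarse head nodes (3 components), the head
  moving rigidly with the clamped pose phi_head = theta_0 + offset;
* total in-plane force and e3-moment free conditions over the cell.

Solving the system yields (thetadot, Xdot0); the active moment density at
the interior joints evolves by the smoothed curvature-switching rate.  The
resulting ODE in z = (X0, theta, m) is integrated with a stiff implicit
variable-order scheme (BDF), from a low-amplitude parabolic initial shape,
until a stable beat pattern emerges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .filament import (
    FlagellumShape,
    stiffness_profile,
    curvature_field,
    reconstruct_positions,
    active_moment_integral,
    hydrodynamic_moment_arms,
    n_active_joints,
)
from .hydrodynamics import (
    HeadMesh,
    build_head_mesh,
    assemble_velocity_operator,
    repulsive_force,
    pose_points,
)
from .moment import smoothed_moment_rate
from .params import DimensionlessParameters

__all__ = [
    "SwimmerState",
    "ForceSolution",
    "BeatRecord",
    "assemble_system",
    "solve_rates",
    "initial_state",
    "integrate",
    "run_to_steady_beat",
    "conservation_residuals",
]


@dataclass
class SwimmerState:
    """Base position, segment-angle field and active-moment field at one instant."""

    shape: FlagellumShape
    m: np.ndarray          # active moment density at interior joints, s <= ell
    time: float = 0.0

    def pack(self) -> np.ndarray:
        return np.concatenate([self.shape.X0, self.shape.theta, self.m])

    @classmethod
    def unpack(cls, z: np.ndarray, N: int, n_active: int, time: float = 0.0) -> "SwimmerState":
        X0 = z[:2]
        theta = z[2:2 + N]
        m = z[2 + N: 2 + N + n_active]
        return cls(shape=FlagellumShape(theta=theta, X0=X0), m=m, time=time)


@dataclass
class ForceSolution:
    """Solved instantaneous rates and force distributions."""

    f: np.ndarray          # (N, 2) hydrodynamic force density per segment
    f_rep: np.ndarray      # (N, 2) repulsive force density per segment
    phi: np.ndarray        # (Q, 3) traction at coarse head nodes
    X0dot: np.ndarray      # (2,)
    thetadot: np.ndarray   # (N,)

    @property
    def phidot(self) -> float:
        """Head angular rate (clamped junction: phidot = thetadot_0)."""
        return float(self.thetadot[0])


class _Discretization:
    """Shape-independent precomputations shared across RHS evaluations."""

    def __init__(self, params: DimensionlessParameters):
        self.params = params
        N = params.N
        self.N = N
        self.h = params.h
        self.s_joints = np.linspace(0.0, 1.0, N + 1)
        self.s_mid = (np.arange(N) + 0.5) * self.h
        self.n_active = n_active_joints(N, params.ell)
        self.E_int = stiffness_profile(self.s_joints[1:-1], params.rho, params.d)
        self.mesh: HeadMesh = build_head_mesh(params.head_semi_axes,
                                              params.head_Q, params.head_refinement)
        self.Q = self.mesh.Q
        # kinematic weights: Xdot at midpoint j = Xdot0 + sum_k W[j,k] thetadot_k n_k
        W = np.tril(np.full((N, N), self.h), k=-1)
        np.fill_diagonal(W, 0.5 * self.h)
        self.W_mid = W
        self.nu = 2 + N + 2 * N + 3 * self.Q
        # unknown layout offsets
        self.o_th = 2
        self.o_f = 2 + N
        self.o_phi = self.o_f + 2 * N


def assemble_system(state: SwimmerState, params: DimensionlessParameters,
                    disc: _Discretization | None = None):
    """Assemble the square linear system A u = b for the instantaneous rates.

    Unknown layout: ``u = [Xdot0 (2), thetadot (N), f (2N), phi (3Q)]``.
    Returns (A, b, aux) where aux carries the geometry and repulsive force
    needed to interpret the solution.
    """
    if disc is None:
        disc = _Discretization(params)
    N, h, Q = disc.N, disc.h, disc.Q
    theta = state.shape.theta
    if not np.all(np.isfinite(state.pack())):
        raise FloatingPointError("non-finite swimmer state")

    X = reconstruct_positions(state.shape)
    Xm = 0.5 * (X[:-1] + X[1:])
    phi_head = theta[0] + params.clamp_offset
    op = assemble_velocity_operator(Xm, disc.mesh, state.shape.X0, phi_head,
                                    params.eps, h)
    f_rep = repulsive_force(Xm, disc.s_mid, op.fine_lab, disc.mesh.fine_weights,
                            params.repulsion_A, params.rep_B,
                            params.rep_delta_excl, params.rep_cutoff, h)

    A = np.zeros((disc.nu, disc.nu))
    b = np.zeros(disc.nu)
    o_th, o_f, o_phi = disc.o_th, disc.o_f, disc.o_phi
    nr_mb = N - 1

    # --- rows 0..N-2: moment balance at the interior joints -----------------
    kappa = np.diff(theta) / h
    I_m = active_moment_integral(state.m, N, params.ell)
    arm_x, arm_y, w_arm = hydrodynamic_moment_arms(X)
    S4 = params.S**4
    cfx = -S4 * w_arm * arm_y                            # coefficient of f_x
    cfy = S4 * w_arm * arm_x                             # coefficient of f_y
    A[:nr_mb, o_f + 0:o_f + 2 * N:2] = cfx
    A[:nr_mb, o_f + 1:o_f + 2 * N:2] = cfy
    b[:nr_mb] = (params.M * I_m - disc.E_int * kappa
                 - cfx @ f_rep[:, 0] - cfy @ f_rep[:, 1])

    # --- rows N-1 .. N-1+2N-1: flagellar no-slip at segment midpoints -------
    r0 = nr_mb
    n_x = -np.sin(theta)
    n_y = np.cos(theta)
    rows_x = slice(r0, r0 + 2 * N, 2)
    rows_y = slice(r0 + 1, r0 + 2 * N, 2)
    A[rows_x, 0] = 1.0
    A[rows_y, 1] = 1.0
    A[rows_x, o_th:o_th + N] = disc.W_mid * n_x[None, :]
    A[rows_y, o_th:o_th + N] = disc.W_mid * n_y[None, :]
    A[r0:r0 + 2 * N, o_f:o_f + 2 * N] -= op.G_ff
    A[r0:r0 + 2 * N, o_phi:] -= op.G_fh
    b[r0:r0 + 2 * N] += op.G_ff @ f_rep.reshape(-1)

    # --- head no-slip at coarse nodes ---------------------------------------
    r1 = r0 + 2 * N
    rel = op.head_lab.copy()
    rel[:, 0] -= state.shape.X0[0]
    rel[:, 1] -= state.shape.X0[1]
    hr_x = slice(r1, r1 + 3 * Q, 3)
    hr_y = slice(r1 + 1, r1 + 3 * Q, 3)
    A[hr_x, 0] = 1.0
    A[hr_y, 1] = 1.0
    # clamped head: phidot = thetadot_0
    A[hr_x, o_th] = -rel[:, 1]
    A[hr_y, o_th] = rel[:, 0]
    A[r1:r1 + 3 * Q, o_f:o_f + 2 * N] -= op.G_hf
    A[r1:r1 + 3 * Q, o_phi:] -= op.G_hh
    b[r1:r1 + 3 * Q] += op.G_hf @ f_rep.reshape(-1)

    # --- closure: total in-plane force and e3 moment vanish -----------------
    r2 = r1 + 3 * Q
    cw = disc.mesh.coarse_weights
    A[r2, o_f + 0:o_f + 2 * N:2] = h
    A[r2 + 1, o_f + 1:o_f + 2 * N:2] = h
    A[r2, o_phi + 0::3] = cw
    A[r2 + 1, o_phi + 1::3] = cw
    b[r2] = -h * np.sum(f_rep[:, 0])
    b[r2 + 1] = -h * np.sum(f_rep[:, 1])
    # e3 moment about the base X0
    mrel = Xm - X[0][None, :]
    A[r2 + 2, o_f + 0:o_f + 2 * N:2] = -h * mrel[:, 1]
    A[r2 + 2, o_f + 1:o_f + 2 * N:2] = h * mrel[:, 0]
    # head: sum_p w_p (Y_p - X0) x phi_nn(p) with phi constant per coarse cell
    wx = np.bincount(disc.mesh.nn,
                     weights=disc.mesh.fine_weights * (op.fine_lab[:, 0] - X[0, 0]),
                     minlength=Q)
    wy = np.bincount(disc.mesh.nn,
                     weights=disc.mesh.fine_weights * (op.fine_lab[:, 1] - X[0, 1]),
                     minlength=Q)
    A[r2 + 2, o_phi + 0::3] = -wy
    A[r2 + 2, o_phi + 1::3] = wx
    b[r2 + 2] = -h * np.sum(mrel[:, 0] * f_rep[:, 1] - mrel[:, 1] * f_rep[:, 0])

    aux = {"op": op, "f_rep": f_rep, "X": X, "Xm": Xm, "kappa": kappa,
           "phi_head": phi_head}
    return A, b, aux


def solve_rates(state: SwimmerState, params: DimensionlessParameters,
                disc: _Discretization | None = None) -> ForceSolution:
    """Solve the instantaneous linear system for rates and forces."""
    if disc is None:
        disc = _Discretization(params)
    A, b, aux = assemble_system(state, params, disc)
    try:
        u = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        cond = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"singular instantaneous system (cond ~ {cond:.2e}); "
            "degenerate discretization") from err
    N, Q = disc.N, disc.Q
    return ForceSolution(
        f=u[disc.o_f:disc.o_f + 2 * N].reshape(N, 2),
        f_rep=aux["f_rep"],
        phi=u[disc.o_phi:].reshape(Q, 3),
        X0dot=u[:2].copy(),
        thetadot=u[disc.o_th:disc.o_th + N].copy(),
    )


def initial_state(params: DimensionlessParameters) -> SwimmerState:
    """Low-amplitude parabolic initial shape, y = 0.1 x^2, unit arclength.

    Segment angles theta_j = atan(0.2 x(sm_j)) at the segment midpoints,
    with x(s) solving the arclength reparameterization from the vertex; the
    base sits at the origin and the moment field is uniform at ``params.m0``.
    """
    def arclen(x):
        a = 0.2
        return 0.5 * (x * np.sqrt(1 + (a * x) ** 2) + np.arcsinh(a * x) / a)

    s_mid = (np.arange(params.N) + 0.5) * params.h
    x_end = brentq(lambda x: arclen(x) - 1.0, 0.0, 2.0)
    x_of_s = np.array([brentq(lambda x: arclen(x) - s, 0.0, x_end + 1e-9)
                       for s in s_mid])
    theta = np.arctan(0.2 * x_of_s)
    m = np.full(n_active_joints(params.N, params.ell), params.m0)
    return SwimmerState(shape=FlagellumShape(theta=theta, X0=np.zeros(2)), m=m)


@dataclass
class BeatRecord:
    """Time series of swimmer states with beat segmentation."""

    params: DimensionlessParameters
    times: np.ndarray          # (nt,)
    X0: np.ndarray             # (nt, 2)
    theta: np.ndarray          # (nt, N)
    m: np.ndarray              # (nt, n_active)
    beat_boundaries: np.ndarray = field(default_factory=lambda: np.empty(0))
    status: str = "ok"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def s_nodes(self) -> np.ndarray:
        """Joint arclength grid [0, 1] (positions live here)."""
        return np.linspace(0.0, 1.0, self.theta.shape[1] + 1)

    @property
    def s_curvature(self) -> np.ndarray:
        """Interior-joint arclength grid (curvature lives here)."""
        N = self.theta.shape[1]
        return np.arange(1, N) / N

    def state_at(self, i: int) -> SwimmerState:
        return SwimmerState(
            shape=FlagellumShape(theta=self.theta[i], X0=self.X0[i]),
            m=self.m[i], time=float(self.times[i]))

    def curvature(self) -> np.ndarray:
        """kappa(s, t) at the interior joints for every step, (nt, N-1)."""
        return np.diff(self.theta, axis=1) / self.params.h

    def force_solution_at(self, i: int, disc: _Discretization | None = None) -> ForceSolution:
        """Re-solve the instantaneous system at recorded step i."""
        return solve_rates(self.state_at(i), self.params, disc)

    def concat(self, other: "BeatRecord") -> "BeatRecord":
        """Append a continuation record (dropping its duplicated first sample)."""
        j = 1 if np.isclose(other.times[0], self.times[-1]) else 0
        return BeatRecord(
            params=self.params,
            times=np.concatenate([self.times, other.times[j:]]),
            X0=np.vstack([self.X0, other.X0[j:]]),
            theta=np.vstack([self.theta, other.theta[j:]]),
            m=np.vstack([self.m, other.m[j:]]),
            status=other.status,
        )


def _make_rhs(params: DimensionlessParameters, disc: _Discretization,
              fast: bool | None = None):
    """Right-hand side z -> zdot of the swimmer ODE.

    Uses the fused jitted kernel when numba is available (asserted equal to
    the transparent numpy assembly in the test suite); set ``fast=False`` to
    force the numpy path.
    """
    N, na = disc.N, disc.n_active
    h = disc.h

    from . import _fast

    if fast is None:
        fast = _fast.HAVE_NUMBA
    if fast:
        mesh = disc.mesh
        args = (np.ascontiguousarray(mesh.coarse),
                np.ascontiguousarray(mesh.fine),
                np.ascontiguousarray(mesh.fine_weights),
                np.ascontiguousarray(mesh.nn),
                np.ascontiguousarray(disc.E_int),
                params.S**4, params.M, params.ell, params.eps, h,
                float(params.head_semi_axes[0]),
                params.kappa_c, params.delta_smooth, params.clamp_offset,
                params.repulsion_A, params.rep_B, params.rep_delta_excl,
                params.rep_cutoff)

        def rhs(t, z):
            z = np.ascontiguousarray(z)
            return _fast.rhs_core(z[2:2 + N], z[:2], z[2 + N:2 + N + na], *args)

        return rhs

    def rhs(t, z):
        state = SwimmerState.unpack(z, N, na, time=t)
        sol = solve_rates(state, params, disc)
        kappa = np.diff(state.shape.theta) / h
        mdot = smoothed_moment_rate(state.m, kappa[:na], params.kappa_c,
                                    params.delta_smooth)
        return np.concatenate([sol.X0dot, sol.thetadot, mdot])

    return rhs


def integrate(state0: SwimmerState, params: DimensionlessParameters,
              t_end: float, t_start: float = 0.0,
              disc: _Discretization | None = None) -> BeatRecord:
    """Integrate the swimmer from ``state0`` to ``t_end`` with a stiff
    implicit variable-order scheme (BDF), reporting at a fixed cadence."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if disc is None:
        disc = _Discretization(params)
    rhs = _make_rhs(params, disc)
    n_rep = max(2, int(round((t_end - t_start) * params.reporting_cadence)) + 1)
    t_eval = np.linspace(t_start, t_end, n_rep)
    sol = solve_ivp(rhs, (t_start, t_end), state0.pack(), method="BDF",
                    t_eval=t_eval, rtol=params.rtol, atol=params.atol)
    if not sol.success:
        raise RuntimeError(f"time integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise FloatingPointError("non-finite state during integration")
    N, na = disc.N, disc.n_active
    y = sol.y.T
    return BeatRecord(params=params, times=sol.t, X0=y[:, :2],
                      theta=y[:, 2:2 + N], m=y[:, 2 + N:2 + N + na])


def run_to_steady_beat(params: DimensionlessParameters,
                       state0: SwimmerState | None = None,
                       window: float = 30.0,
                       disc: _Discretization | None = None):
    """Integrate in windows until a stable beat pattern emerges.

    Steady when the relative L2 distance between successive per-beat
    mean-|kappa| profiles falls below ``params.steady_rtol`` for two
    consecutive beat pairs; ``no_beat`` when the recent oscillation
    amplitude of theta(0, t) falls below ``params.no_beat_atol``;
    ``not_converged`` at ``params.max_time``.

    Returns (record, status, period) with status in
    {"converged", "no_beat", "not_converged"} and the mean beat period
    (nan unless beats were found).
    """
    from .analysis import segment_beats, beat_profiles

    if disc is None:
        disc = _Discretization(params)
    state = initial_state(params) if state0 is None else state0
    record = None
    t0 = 0.0
    while t0 < params.max_time:
        t1 = min(t0 + window, params.max_time)
        piece = integrate(state, params, t1, t_start=t0, disc=disc)
        record = piece if record is None else record.concat(piece)
        state = record.state_at(len(record.times) - 1)
        t0 = t1

        boundaries = segment_beats(record)
        record.beat_boundaries = boundaries
        # probe for quiescence over the trailing window: no recent beat
        # boundary and a sub-floor oscillation amplitude
        t_probe = record.times[-1] - 0.5 * window
        probe = record.times >= t_probe
        sig = record.theta[probe, 0]
        amp = 0.5 * (np.max(sig) - np.min(sig))
        # floor: absolute, or 5% of the largest excursion seen (a decaying
        # spiral toward equilibrium never reaches an absolute floor quickly)
        amp_floor = max(params.no_beat_atol,
                        0.05 * 0.5 * np.ptp(record.theta[:, 0]))
        recent = boundaries[boundaries > t_probe] if boundaries.size else boundaries
        if t0 >= 2 * window and recent.size == 0 and amp < amp_floor:
            return record, "no_beat", float("nan")
        if boundaries.size >= 4:
            profiles = beat_profiles(record, boundaries)
            period = float(np.mean(np.diff(boundaries[-4:])))
            d = []
            for a, bb in zip(profiles[-3:-1], profiles[-2:]):
                scale = np.linalg.norm(bb) or 1.0
                d.append(np.linalg.norm(a - bb) / scale)
            if len(d) >= 2 and max(d) < params.steady_rtol:
                return record, "converged", period
    boundaries = record.beat_boundaries
    period = float(np.mean(np.diff(boundaries))) if boundaries.size >= 2 else float("nan")
    t_probe = record.times[-1] - 0.5 * window
    sig = record.theta[record.times >= t_probe, 0]
    amp = 0.5 * (np.max(sig) - np.min(sig))
    amp_floor = max(params.no_beat_atol, 0.05 * 0.5 * np.ptp(record.theta[:, 0]))
    recent = boundaries[boundaries > t_probe] if boundaries.size else boundaries
    if recent.size == 0 and amp < amp_floor:
        return record, "no_beat", float("nan")
    return record, "not_converged", period


def conservation_residuals(record: BeatRecord, stride: int = 1,
                           disc: _Discretization | None = None) -> np.ndarray:
    """Relative total-force/moment residuals at recorded steps.

    Independently recomputes, by direct summation over all surface and line
    forces with the discretization's quadrature weights, the total in-plane
    force and e3 moment of (f, phi, f_rep), and returns them scaled by the
    force norm, as an (n_checked, 3) array [|Fx|, |Fy|, |Mz|] / scale.
    """
    if disc is None:
        disc = _Discretization(record.params)
    h = disc.h
    out = []
    for i in range(0, len(record.times), stride):
        st = record.state_at(i)
        sol = solve_rates(st, record.params, disc)
        X = reconstruct_positions(st.shape)
        Xm = 0.5 * (X[:-1] + X[1:])
        ftot = sol.f + sol.f_rep
        fine = pose_points(disc.mesh.fine, st.shape.X0,
                           st.shape.theta[0] + record.params.clamp_offset,
                           disc.mesh.junction)
        phi_fine = sol.phi[disc.mesh.nn]
        w = disc.mesh.fine_weights
        F = h * ftot.sum(axis=0) + (w[:, None] * phi_fine[:, :2]).sum(axis=0)
        rel_f = Xm - X[0]
        rel_h = fine[:, :2] - X[0][None, :]
        Mz = (h * (rel_f[:, 0] * ftot[:, 1] - rel_f[:, 1] * ftot[:, 0]).sum()
              + (w * (rel_h[:, 0] * phi_fine[:, 1] - rel_h[:, 1] * phi_fine[:, 0])).sum())
        scale = h * np.abs(ftot).sum() + (w[:, None] * np.abs(phi_fine[:, :2])).sum()
        scale = scale if scale > 0 else 1.0
        out.append([abs(F[0]) / scale, abs(F[1]) / scale, abs(Mz) / scale])
    return np.asarray(out)
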