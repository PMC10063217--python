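"""Geometrically nonlinear planar inextensible filament.

The flagellum has unit dimensionless length and is discretized as a chain
of N straight segments of length h = 1/N; the state is the tangent angle
of each segment against the lab horizontal plus the base position X0.
Joint positions follow by the exact polyline sum

    X_{j+1} = X_j + h (cos theta_j, sin theta_j),

which makes inextensibility exact by construction, and signed curvature is
the exact joint difference kappa_i = (theta_i - theta_{i-1}) / h at the
N-1 interior joints (positive = counterclockwise turning).  The staircase
representation is the standard bead/segment discretization of regularized
Stokeslet filament models; unlike node-centered differencing of a nodal
angle field it has no zigzag null mode, so the discrete elastica cannot
develop sawtooth instabilities.

Bending stiffness tapers from rho at the base to 1 at arclength d:

    E(s) = (rho - 1) ((s - d)/d)^2 + 1   for s <= d,   E = 1 beyond.

The elastohydrodynamic moment balance is collocated at the interior
joints; arclength integrals use the trapezoid rule on joint values (active
moment) and the midpoint rule per segment (hydrodynamic moment arms),
matching the piecewise-constant force discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlagellumShape",
    "MomentField",
    "stiffness_profile",
    "reconstruct_positions",
    "midpoints",
    "curvature_field",
    "active_moment_integral",
    "moment_balance_residual",
    "elastic_energy",
    "n_active_joints",
    "active_s",
]


@dataclass
class FlagellumShape:
    """Staircase tangent-angle description of the flagellum at one instant.

    ``theta`` holds the N segment angles (radians); ``X0`` is the base
    (head junction) position in flagellar lengths.
    """

    theta: np.ndarray
    X0: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.X0 = np.asarray(self.X0, dtype=float)
        if self.theta.ndim != 1 or self.theta.size < 2:
            raise ValueError("theta must be a 1-d array with at least 2 segments")
        if self.X0.shape != (2,):
            raise ValueError("X0 must be a 2-vector")

    @property
    def N(self) -> int:
        return self.theta.size

    @property
    def h(self) -> float:
        return 1.0 / self.N

    @property
    def s_joints(self) -> np.ndarray:
        """Arclength of the N+1 joints (segment endpoints), [0, 1]."""
        return np.linspace(0.0, 1.0, self.N + 1)

    @property
    def s_mid(self) -> np.ndarray:
        """Arclength of the N segment midpoints."""
        return (np.arange(self.N) + 0.5) * self.h


@dataclass
class MomentField:
    """Active moment density at the interior joints with s <= ell."""

    m: np.ndarray
    s_nodes: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.s_nodes = np.asarray(self.s_nodes, dtype=float)
        if self.m.shape != self.s_nodes.shape:
            raise ValueError("m and s_nodes must have matching shapes")
        if not np.all(np.isfinite(self.m)):
            raise ValueError("non-finite moment field")


def n_active_joints(N: int, ell: float) -> int:
    """Number of interior joints (s = h .. (N-1)h) with s <= ell."""
    return min(N - 1, int(np.floor(ell * N + 1e-9)))


def active_s(N: int, ell: float) -> np.ndarray:
    """Arclength of the active interior joints."""
    na = n_active_joints(N, ell)
    return np.arange(1, na + 1) / N


def stiffness_profile(s, rho, d):
    """Dimensionless bending stiffness E(s) of the tapered flagellum.

    E decreases quadratically from rho at the base to 1 at arclength ``d``
    and is 1 beyond; continuous at s = d.
    """
    if d <= 0 or d > 1:
        raise ValueError("taper fraction d must lie in (0, 1]")
    if rho < 1:
        raise ValueError("rho must be >= 1")
    s = np.asarray(s, dtype=float)
    if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
        raise ValueError("arclength out of [0, 1]")
    E = np.where(s <= d, (rho - 1.0) * ((s - d) / d) ** 2 + 1.0, 1.0)
    return E if E.ndim else float(E)


def reconstruct_positions(shape: FlagellumShape) -> np.ndarray:
    """Joint positions X(s) = X0 + int_0^s (cos theta, sin theta) ds'.

    The integral is the exact polyline sum over the staircase angles;
    X(0) = X0 exactly and the polyline length is exactly 1.  Returns an
    (N+1, 2) array.
    """
    t = np.column_stack([np.cos(shape.theta), np.sin(shape.theta)])
    X = np.empty((shape.N + 1, 2))
    X[0] = shape.X0
    X[1:] = shape.X0 + np.cumsum(shape.h * t, axis=0)
    return X


def midpoints(shape: FlagellumShape) -> np.ndarray:
    """Segment midpoint positions, (N, 2)."""
    X = reconstruct_positions(shape)
    return 0.5 * (X[:-1] + X[1:])


def curvature_field(shape_or_theta, h: float | None = None) -> np.ndarray:
    """Signed curvature kappa = d theta / ds at the N-1 interior joints.

    Exact difference of adjacent segment angles; for theta sampled from a
    linear profile the result is exact, for smooth profiles second-order
    accurate at the joints.
    """
    if isinstance(shape_or_theta, FlagellumShape):
        theta, h = shape_or_theta.theta, shape_or_theta.h
    else:
        theta = np.asarray(shape_or_theta, dtype=float)
        if h is None:
            h = 1.0 / theta.size
    if theta.size < 2:
        raise ValueError("need at least 2 segments for curvature")
    return np.diff(theta) / h


def active_moment_integral(m_active: np.ndarray, N: int, ell: float) -> np.ndarray:
    """I(s_i) = int_{s_i}^1 m(s') H(ell - s') ds' at interior joints.

    ``m_active`` holds joint values on the active joints (s <= ell); the
    integrand vanishes over the passive end piece.  Trapezoid rule on the
    active joints; returns the value at every interior joint (N-1,).
    """
    h = 1.0 / N
    na = m_active.size
    cum = np.concatenate([[0.0], np.cumsum(0.5 * h * (m_active[:-1] + m_active[1:]))])
    # support may extend past the last interior joint (e.g. ell = 1); carry
    # the last joint value constantly over the remaining tail
    tail = max(min(ell, 1.0) - na * h, 0.0) * m_active[-1]
    out = np.zeros(N - 1)
    out[:na] = cum[-1] - cum + tail
    return out


def hydrodynamic_moment_arms(X: np.ndarray):
    """Moment-arm geometry of the hydrodynamic force integral.

    Collocation at the N-1 interior joints; the force is piecewise constant
    per segment at the N midpoints.  Returns (arm_x, arm_y, w) of shape
    (N-1, N): row i carries the arm from joint i+1 to the midpoint of
    segment j, with quadrature weight h for the distal segments j >= i+1
    and zero proximally.
    """
    Xm = 0.5 * (X[:-1] + X[1:])
    N = Xm.shape[0]
    h = 1.0 / N
    arm_x = Xm[:, 0][None, :] - X[1:-1, 0][:, None]
    arm_y = Xm[:, 1][None, :] - X[1:-1, 1][:, None]
    w = np.zeros((N - 1, N))
    for i in range(N - 1):
        w[i, i + 1:] = h
    return arm_x, arm_y, w


def moment_balance_residual(shape: FlagellumShape, m_active: np.ndarray,
                            f_mid: np.ndarray, params) -> np.ndarray:
    """Residual of the elastohydrodynamic moment balance,

        E(s) d theta/ds - M int_s^1 m H(ell - s') ds'
            + S^4 e3 . int_s^1 (X(s') - X(s)) x f(s') ds'  =  0,

    collocated at the N-1 interior joints.  ``f_mid`` is the in-plane
    force per unit length exerted by the flagellum on the fluid, constant
    per segment.  Zero at a solution of the coupled swimmer system.
    """
    N = shape.N
    if f_mid.shape != (N, 2):
        raise ValueError(f"f_mid must have shape ({N}, 2)")
    na = n_active_joints(N, params.ell)
    if m_active.shape != (na,):
        raise ValueError(f"m_active must have shape ({na},) for this grid")
    s_int = shape.s_joints[1:-1]
    E_int = stiffness_profile(s_int, params.rho, params.d)
    kappa = curvature_field(shape)
    I_m = active_moment_integral(m_active, N, params.ell)
    X = reconstruct_positions(shape)
    arm_x, arm_y, w = hydrodynamic_moment_arms(X)
    cross = arm_x * f_mid[:, 1][None, :] - arm_y * f_mid[:, 0][None, :]
    hydro = params.S**4 * np.sum(w * cross, axis=1)
    return E_int * kappa - params.M * I_m + hydro


def elastic_energy(shape: FlagellumShape, rho: float, d: float) -> float:
    """Bending energy (1/2) sum_joints E kappa^2 h of the discrete chain."""
    s_int = shape.s_joints[1:-1]
    E = stiffness_profile(s_int, rho, d)
    kappa = curvature_field(shape)
    return float(0.5 * shape.h * np.sum(E * kappa**2))
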