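"""Nonlocal Stokes-flow coupling via the method of regularized Stokeslets.

At very low Reynolds number the flow driven by a spatially concentrated
smoothed force (blob) has the closed-form regularized Stokeslet kernel

    S_ij(x, y) = [delta_ij (r^2 + 2 eps^2) + r_i r_j] / (8 pi mu r_eps^3),

with r = x - y and r_eps^2 = r^2 + eps^2; the kernel is finite at x = y so
boundary-integral collocation needs no singularity treatment.  The
three-dimensional ellipsoidal head is discretized with a two-grid
nearest-neighbor (NEAREST) scheme: tractions live on a coarse node set,
surface quadrature on a finer set whose weights are accumulated onto the
nearest coarse node.  The viscosity is scaled to one in the dimensionless
assembly.

A short-range repulsive force between flagellar segments and between the
flagellum and the head regularizes self-intersecting configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HeadMesh",
    "reg_stokeslet",
    "blob",
    "build_head_mesh",
    "stokeslet_matrix",
    "assemble_velocity_operator",
    "VelocityOperator",
    "rigid_body_velocity",
    "repulsive_force",
    "pose_points",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def reg_stokeslet(x, y, epsilon, mu: float = 1.0) -> np.ndarray:
    """Regularized Stokeslet tensor S_ij(x, y) for a single point pair.

    Returns the 3x3 mobility tensor; finite at x = y, where it equals
    ``I / (4 pi mu eps)``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    r = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    r2 = float(r @ r)
    re = np.sqrt(r2 + epsilon**2)
    return (np.eye(3) * (r2 + 2.0 * epsilon**2) + np.outer(r, r)) / (8.0 * np.pi * mu * re**3)


def blob(x, epsilon) -> float | np.ndarray:
    """Blob (mollified delta) generating the regularized Stokeslet.

    ``psi_eps(x) = 15 eps^4 / [8 pi (|x|^2 + eps^2)^(7/2)]``; radially
    symmetric, integrates to one over all space.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    r2 = np.sum(x * x, axis=-1)
    val = 15.0 * epsilon**4 / (8.0 * np.pi * (r2 + epsilon**2) ** 3.5)
    return float(val[0]) if val.size == 1 else val


def stokeslet_matrix(targets: np.ndarray, sources: np.ndarray, epsilon: float,
                     mu: float = 1.0) -> np.ndarray:
    """Dense kernel array S[t, i, s, j] over target and source point sets.

    ``targets`` (nt, 3) and ``sources`` (ns, 3); returns (nt, 3, ns, 3).
    """
    r = targets[:, None, :] - sources[None, :, :]          # (nt, ns, 3)
    r2 = (r * r).sum(axis=-1)
    coef = 1.0 / (8.0 * np.pi * mu * (r2 + epsilon**2) ** 1.5)
    out = r[:, :, :, None] * r[:, :, None, :]              # (nt, ns, 3, 3)
    diag = r2 + 2.0 * epsilon**2
    out[:, :, 0, 0] += diag
    out[:, :, 1, 1] += diag
    out[:, :, 2, 2] += diag
    out *= coef[:, :, None, None]
    return np.ascontiguousarray(out.transpose(0, 2, 1, 3))


@dataclass
class HeadMesh:
    """Two-grid NEAREST discretization of the ellipsoidal head surface.

    Body frame: ellipsoid centered at the origin with semi-axes
    ``(a, b, c)``; the flagellum attaches at the vertex ``(+a, 0, 0)`` and
    the beat plane is z = 0.  ``coarse`` holds the traction nodes,
    ``fine``/``fine_weights`` the quadrature nodes (weights sum to the
    surface area), and ``nn`` maps each fine node to its nearest coarse
    node (ties broken by lowest index).
    """

    semi_axes: np.ndarray
    coarse: np.ndarray        # (Q, 3)
    fine: np.ndarray          # (Qf, 3)
    fine_weights: np.ndarray  # (Qf,)
    nn: np.ndarray            # (Qf,) int

    @property
    def Q(self) -> int:
        return self.coarse.shape[0]

    @property
    def Qf(self) -> int:
        return self.fine.shape[0]

    @property
    def junction(self) -> np.ndarray:
        """Body-frame attachment point of the flagellum."""
        return np.array([self.semi_axes[0], 0.0, 0.0])

    @property
    def coarse_weights(self) -> np.ndarray:
        """Quadrature weight accumulated onto each coarse node."""
        return np.bincount(self.nn, weights=self.fine_weights, minlength=self.Q)

    @property
    def accum(self) -> np.ndarray:
        """(Qf, Q) accumulation matrix: accum[p, nn(p)] = fine weight p."""
        if not hasattr(self, "_accum"):
            P = np.zeros((self.Qf, self.Q))
            P[np.arange(self.Qf), self.nn] = self.fine_weights
            self._accum = P
        return self._accum


def _half_fibonacci_sphere(k: int) -> np.ndarray:
    """k quasi-uniform unit-sphere points with z > 0 (Fibonacci lattice)."""
    i = np.arange(k)
    z = (i + 0.5) / k              # uniform in z on (0, 1): upper hemisphere
    phi = _GOLDEN_ANGLE * i
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _symmetric_ellipsoid_points(n_half: int, semi_axes: np.ndarray):
    """Mirror-symmetric (z -> -z) quasi-uniform points on the ellipsoid.

    Returns (points (2*n_half, 3), weights) with exact per-point surface
    Jacobian of the sphere-to-ellipsoid map: for a unit normal n, the area
    scale is ``abc * |diag(1/a, 1/b, 1/c) n|``.
    """
    a, b, c = semi_axes
    upper = _half_fibonacci_sphere(n_half)
    pts_sph = np.vstack([upper, upper * np.array([1.0, 1.0, -1.0])])
    pts = pts_sph * semi_axes[None, :]
    jac = a * b * c * np.sqrt(np.sum((pts_sph / semi_axes[None, :]) ** 2, axis=1))
    # each hemisphere point represents sphere area 2*pi/n_half
    weights = (2.0 * np.pi / n_half) * jac
    return pts, weights


def build_head_mesh(semi_axes, target_Q: int = 16, refinement: int = 4) -> HeadMesh:
    """Build the two-grid NEAREST mesh on the ellipsoid surface.

    ``target_Q`` coarse traction nodes (rounded to even for exact z -> -z
    symmetry) and ``refinement * target_Q`` fine quadrature nodes, both from
    a mirrored Fibonacci lattice.  Fine weights sum to the ellipsoid
    surface area (exact Jacobian, quasi-uniform lattice).
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if semi_axes.shape != (3,) or np.any(semi_axes <= 0):
        raise ValueError("semi_axes must be 3 positive numbers")
    if target_Q < 6:
        raise ValueError("need at least 6 coarse nodes")
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    qh = max(3, int(round(target_Q / 2)))
    coarse, _ = _symmetric_ellipsoid_points(qh, semi_axes)
    fine, fw = _symmetric_ellipsoid_points(qh * refinement, semi_axes)
    d2 = np.sum((fine[:, None, :] - coarse[None, :, :]) ** 2, axis=2)
    nn = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    counts = np.bincount(nn, minlength=coarse.shape[0])
    if np.any(counts == 0):
        # guarantee every traction node at least one quadrature node by
        # snapping the nearest fine node to any orphaned coarse node
        for q in np.flatnonzero(counts == 0):
            nn[np.argmin(d2[:, q])] = q
    return HeadMesh(semi_axes=semi_axes, coarse=coarse, fine=fine,
                    fine_weights=fw, nn=nn)


def pose_points(points_body: np.ndarray, X0: np.ndarray, phi: float,
                junction: np.ndarray) -> np.ndarray:
    """Pose body-frame head points in the lab: rotate by phi about e3 and
    translate so the junction vertex lands on the flagellar base X0."""
    cph, sph = np.cos(phi), np.sin(phi)
    R = np.array([[cph, -sph, 0.0], [sph, cph, 0.0], [0.0, 0.0, 1.0]])
    rel = points_body - junction[None, :]
    out = rel @ R.T
    out[:, 0] += X0[0]
    out[:, 1] += X0[1]
    return out


def rigid_body_velocity(X0dot, phidot: float, Y, X0) -> np.ndarray:
    """Planar rigid-body velocity  Xdot0 + phidot e3 x (Y - X0)  at Y."""
    single = np.asarray(Y).ndim == 1
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    r = Y.copy()
    r[:, 0] -= X0[0]
    r[:, 1] -= X0[1]
    v = np.zeros_like(Y)
    v[:, 0] = X0dot[0] - phidot * r[:, 1]
    v[:, 1] = X0dot[1] + phidot * r[:, 0]
    return v[0] if single else v


@dataclass
class VelocityOperator:
    """Dense discrete velocity operator of the coupled boundary integrals.

    Maps (f on flagellar segments, phi on coarse head nodes) to fluid
    velocities at the flagellar segment midpoints (in-plane components) and
    the coarse head nodes (all three components).

    Blocks (with N segments and Q coarse nodes):

    * ``G_ff`` (2N, 2N): line quadrature of the kernel along the centerline
      (piecewise-constant force per segment, weight h, midpoint collocation);
    * ``G_fh`` (2N, 3Q): head-to-flagellum, NEAREST summation;
    * ``G_hf`` (3Q, 2N): flagellum-to-head;
    * ``G_hh`` (3Q, 3Q): head-to-head, NEAREST summation.
    """

    G_ff: np.ndarray
    G_fh: np.ndarray
    G_hf: np.ndarray
    G_hh: np.ndarray
    head_lab: np.ndarray       # posed coarse nodes (Q, 3)
    fine_lab: np.ndarray       # posed fine nodes (Qf, 3)

    def flagellum_velocity(self, f: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """In-plane velocities at segment midpoints, (N, 2)."""
        v = self.G_ff @ f.reshape(-1) + self.G_fh @ phi.reshape(-1)
        return v.reshape(-1, 2)

    def head_velocity(self, f: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Velocities at coarse head nodes, (Q, 3)."""
        v = self.G_hf @ f.reshape(-1) + self.G_hh @ phi.reshape(-1)
        return v.reshape(-1, 3)


def _nearest_accumulate(kernel: np.ndarray, mesh: "HeadMesh") -> np.ndarray:
    """Accumulate fine-node kernel columns onto coarse traction nodes.

    ``kernel``: (nt, ci, Qf, 3) kernel at fine quadrature nodes; returns
    (nt * ci, 3 * Q) with column blocks ``sum_{p: nn(p)=q} w_p K[..., p, :]``.
    """
    nt, ci, qf, _ = kernel.shape
    acc = np.tensordot(kernel, mesh.accum, axes=([2], [0]))  # (nt, ci, 3, Q)
    acc = acc.transpose(0, 1, 3, 2)
    return np.ascontiguousarray(acc).reshape(nt * ci, 3 * mesh.Q)


def assemble_velocity_operator(midpoints: np.ndarray, mesh: HeadMesh,
                               X0: np.ndarray, phi_head: float,
                               epsilon: float, h: float) -> VelocityOperator:
    """Assemble the dense velocity operator for the current configuration.

    ``midpoints``: (N, 2) in-plane flagellar segment midpoints; the head
    pose is (X0, phi_head) applied to the body-frame mesh.
    """
    N = midpoints.shape[0]
    mid3 = np.zeros((N, 3))
    mid3[:, :2] = midpoints
    coarse_lab = pose_points(mesh.coarse, X0, phi_head, mesh.junction)
    fine_lab = pose_points(mesh.fine, X0, phi_head, mesh.junction)

    # one kernel evaluation over all collocation/source points, then blocks
    targets = np.vstack([mid3, coarse_lab])
    sources = np.vstack([mid3, fine_lab])
    K = stokeslet_matrix(targets, sources, epsilon)   # (N+Q, 3, N+Qf, 3)

    G_ff = (h * K[:N, :2, :N, :2]).reshape(2 * N, 2 * N)
    G_fh = _nearest_accumulate(K[:N, :2, N:], mesh)
    G_hf = (h * K[N:, :, :N, :2]).reshape(3 * mesh.Q, 2 * N)
    G_hh = _nearest_accumulate(K[N:, :, N:], mesh)

    return VelocityOperator(G_ff=G_ff, G_fh=G_fh, G_hf=G_hf, G_hh=G_hh,
                            head_lab=coarse_lab, fine_lab=fine_lab)


def repulsive_force(midpoints: np.ndarray, s_mid: np.ndarray,
                    fine_lab: np.ndarray, fine_weights: np.ndarray,
                    A: float, B: float, delta_excl: float, cutoff: float,
                    h: float) -> np.ndarray:
    """Short-range repulsive force density at the flagellar midpoints.

    Pairwise kernel ``A exp(-B d) (1 - exp(-B d))`` along the unit
    separation vector, integrated over the flagellar centerline outside the
    arclength exclusion window |s - s'| < delta_excl and over the head
    surface; pairs farther apart than ``cutoff`` contribute exactly zero.
    Returns the in-plane (N, 2) force density (out-of-plane head
    contributions cancel by mesh symmetry).
    """
    if A < 0 or B <= 0 or delta_excl <= 0 or cutoff <= 0:
        raise ValueError("repulsion parameters must be positive")
    N = midpoints.shape[0]
    out = np.zeros((N, 2))
    if A == 0:
        return out
    # flagellum-flagellum: evaluate the kernel only on admissible close pairs
    dx = midpoints[:, None, :] - midpoints[None, :, :]
    d2 = np.sum(dx * dx, axis=2)
    mask = (np.abs(s_mid[:, None] - s_mid[None, :]) >= delta_excl) & (d2 < cutoff**2) & (d2 > 0)
    ti, si = np.nonzero(mask)
    if ti.size:
        dist = np.sqrt(d2[ti, si])
        e = np.exp(-B * dist)
        mag = A * e * (1.0 - e) / dist * h
        np.add.at(out, ti, mag[:, None] * dx[ti, si])
    # flagellum-head (fine surface quadrature)
    dxh = midpoints[:, None, :] - fine_lab[None, :, :2]
    d2h = np.sum(dxh * dxh, axis=2) + fine_lab[None, :, 2] ** 2
    ti, pi = np.nonzero((d2h < cutoff**2) & (d2h > 0))
    if ti.size:
        dist = np.sqrt(d2h[ti, pi])
        e = np.exp(-B * dist)
        mag = A * e * (1.0 - e) / dist * fine_weights[pi]
        np.add.at(out, ti, mag[:, None] * dxh[ti, pi])
    return out
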