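"""Fused numba kernel for the instantaneous swimmer solve.

The time integrator evaluates the right-hand side tens of thousands of
times per run; this module fuses geometry, kernel assembly, the dense
linear solve and the switching law into a single jitted function.  It
mirrors, term by term, the transparent numpy assembly in
:mod:`archswim.assembly` (the two are asserted equal to 1e-12 in the test
suite); the numpy path remains the reference implementation and is used
for all one-off solves.

When numba is unavailable the package silently falls back to the numpy
path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def rhs_core(theta, X0, m,
             coarse_b, fine_b, fine_w, nn,
             E_int, S4, Mpar, ell, eps, h, junction_x,
             kc, delta, clamp_offset,
             Arep, Brep, dexcl, cutoff):
    N = theta.shape[0]
    Q = coarse_b.shape[0]
    Qf = fine_b.shape[0]
    na = m.shape[0]
    nu = 2 + N + 2 * N + 3 * Q
    o_th = 2
    o_f = 2 + N
    o_phi = o_f + 2 * N

    # ----- geometry ---------------------------------------------------------
    X = np.empty((N + 1, 2))
    X[0, 0] = X0[0]
    X[0, 1] = X0[1]
    ct = np.cos(theta)
    st = np.sin(theta)
    for j in range(N):
        X[j + 1, 0] = X[j, 0] + h * ct[j]
        X[j + 1, 1] = X[j, 1] + h * st[j]
    Xm = 0.5 * (X[:-1] + X[1:])

    phi_head = theta[0] + clamp_offset
    cph = np.cos(phi_head)
    sph = np.sin(phi_head)
    coarse = np.empty((Q, 3))
    for q in range(Q):
        rx = coarse_b[q, 0] - junction_x
        ry = coarse_b[q, 1]
        coarse[q, 0] = X0[0] + cph * rx - sph * ry
        coarse[q, 1] = X0[1] + sph * rx + cph * ry
        coarse[q, 2] = coarse_b[q, 2]
    fine = np.empty((Qf, 3))
    for p in range(Qf):
        rx = fine_b[p, 0] - junction_x
        ry = fine_b[p, 1]
        fine[p, 0] = X0[0] + cph * rx - sph * ry
        fine[p, 1] = X0[1] + sph * rx + cph * ry
        fine[p, 2] = fine_b[p, 2]

    # ----- repulsive force at midpoints ------------------------------------
    frep = np.zeros((N, 2))
    if Arep > 0.0:
        cut2 = cutoff * cutoff
        for j in range(N):
            sj = (j + 0.5) * h
            for jp in range(N):
                if abs(sj - (jp + 0.5) * h) < dexcl:
                    continue
                dx = Xm[j, 0] - Xm[jp, 0]
                dy = Xm[j, 1] - Xm[jp, 1]
                d2 = dx * dx + dy * dy
                if d2 >= cut2 or d2 <= 0.0:
                    continue
                dist = np.sqrt(d2)
                e = np.exp(-Brep * dist)
                mag = Arep * e * (1.0 - e) / dist * h
                frep[j, 0] += mag * dx
                frep[j, 1] += mag * dy
            for p in range(Qf):
                dx = Xm[j, 0] - fine[p, 0]
                dy = Xm[j, 1] - fine[p, 1]
                dz = -fine[p, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 >= cut2 or d2 <= 0.0:
                    continue
                dist = np.sqrt(d2)
                e = np.exp(-Brep * dist)
                mag = Arep * e * (1.0 - e) / dist * fine_w[p]
                frep[j, 0] += mag * dx
                frep[j, 1] += mag * dy

    A = np.zeros((nu, nu))
    b = np.zeros(nu)
    c8p = 1.0 / (8.0 * np.pi)
    e2 = eps * eps

    # ----- moment balance at interior joints --------------------------------
    # active moment integral I(joint i), i = 1..N-1 (trapezoid + tail)
    ellc = min(ell, 1.0)
    tail = (ellc - na * h) * m[na - 1] if ellc - na * h > 0.0 else 0.0
    I = np.zeros(N - 1)
    cum = np.zeros(na)
    for k in range(1, na):
        cum[k] = cum[k - 1] + 0.5 * h * (m[k - 1] + m[k])
    total = cum[na - 1] + tail
    for i in range(1, N):
        if i <= na:
            I[i - 1] = total - cum[i - 1]
        else:
            I[i - 1] = 0.0

    for i in range(1, N):
        row = i - 1
        kap = (theta[i] - theta[i - 1]) / h
        bi = Mpar * I[i - 1] - E_int[i - 1] * kap
        for j in range(i, N):
            ax = Xm[j, 0] - X[i, 0]
            ay = Xm[j, 1] - X[i, 1]
            cfx = -S4 * h * ay
            cfy = S4 * h * ax
            A[row, o_f + 2 * j] = cfx
            A[row, o_f + 2 * j + 1] = cfy
            bi -= cfx * frep[j, 0] + cfy * frep[j, 1]
        b[row] = bi

    # ----- flagellar no-slip at midpoints ----------------------------------
    r0 = N - 1
    for j in range(N):
        rx_ = r0 + 2 * j
        ry_ = rx_ + 1
        A[rx_, 0] = 1.0
        A[ry_, 1] = 1.0
        for k in range(j + 1):
            w = h if k < j else 0.5 * h
            A[rx_, o_th + k] = -w * st[k]
            A[ry_, o_th + k] = w * ct[k]
        bx = 0.0
        by = 0.0
        for jp in range(N):
            dx = Xm[j, 0] - Xm[jp, 0]
            dy = Xm[j, 1] - Xm[jp, 1]
            r2 = dx * dx + dy * dy
            re3 = (r2 + e2) ** 1.5
            co = c8p / re3
            diag = r2 + 2.0 * e2
            sxx = co * (diag + dx * dx)
            sxy = co * dx * dy
            syy = co * (diag + dy * dy)
            A[rx_, o_f + 2 * jp] -= h * sxx
            A[rx_, o_f + 2 * jp + 1] -= h * sxy
            A[ry_, o_f + 2 * jp] -= h * sxy
            A[ry_, o_f + 2 * jp + 1] -= h * syy
            bx += h * (sxx * frep[jp, 0] + sxy * frep[jp, 1])
            by += h * (sxy * frep[jp, 0] + syy * frep[jp, 1])
        for p in range(Qf):
            dx = Xm[j, 0] - fine[p, 0]
            dy = Xm[j, 1] - fine[p, 1]
            dz = -fine[p, 2]
            r2 = dx * dx + dy * dy + dz * dz
            re3 = (r2 + e2) ** 1.5
            co = fine_w[p] * c8p / re3
            diag = r2 + 2.0 * e2
            q = nn[p]
            A[rx_, o_phi + 3 * q] -= co * (diag + dx * dx)
            A[rx_, o_phi + 3 * q + 1] -= co * dx * dy
            A[rx_, o_phi + 3 * q + 2] -= co * dx * dz
            A[ry_, o_phi + 3 * q] -= co * dx * dy
            A[ry_, o_phi + 3 * q + 1] -= co * (diag + dy * dy)
            A[ry_, o_phi + 3 * q + 2] -= co * dy * dz
        b[rx_] = bx
        b[ry_] = by

    # ----- head no-slip at coarse nodes -------------------------------------
    r1 = r0 + 2 * N
    for q in range(Q):
        relx = coarse[q, 0] - X0[0]
        rely = coarse[q, 1] - X0[1]
        rowx = r1 + 3 * q
        A[rowx, 0] = 1.0
        A[rowx + 1, 1] = 1.0
        A[rowx, o_th] = -rely
        A[rowx + 1, o_th] = relx
        bx = 0.0
        by = 0.0
        bz = 0.0
        for jp in range(N):
            dx = coarse[q, 0] - Xm[jp, 0]
            dy = coarse[q, 1] - Xm[jp, 1]
            dz = coarse[q, 2]
            r2 = dx * dx + dy * dy + dz * dz
            re3 = (r2 + e2) ** 1.5
            co = c8p / re3
            diag = r2 + 2.0 * e2
            sxx = co * (diag + dx * dx)
            sxy = co * dx * dy
            syy = co * (diag + dy * dy)
            sxz = co * dx * dz
            syz = co * dy * dz
            A[rowx, o_f + 2 * jp] -= h * sxx
            A[rowx, o_f + 2 * jp + 1] -= h * sxy
            A[rowx + 1, o_f + 2 * jp] -= h * sxy
            A[rowx + 1, o_f + 2 * jp + 1] -= h * syy
            A[rowx + 2, o_f + 2 * jp] -= h * sxz
            A[rowx + 2, o_f + 2 * jp + 1] -= h * syz
            bx += h * (sxx * frep[jp, 0] + sxy * frep[jp, 1])
            by += h * (sxy * frep[jp, 0] + syy * frep[jp, 1])
            bz += h * (sxz * frep[jp, 0] + syz * frep[jp, 1])
        for p in range(Qf):
            dx = coarse[q, 0] - fine[p, 0]
            dy = coarse[q, 1] - fine[p, 1]
            dz = coarse[q, 2] - fine[p, 2]
            r2 = dx * dx + dy * dy + dz * dz
            re3 = (r2 + e2) ** 1.5
            co = fine_w[p] * c8p / re3
            diag = r2 + 2.0 * e2
            qq = nn[p]
            A[rowx, o_phi + 3 * qq] -= co * (diag + dx * dx)
            A[rowx, o_phi + 3 * qq + 1] -= co * dx * dy
            A[rowx, o_phi + 3 * qq + 2] -= co * dx * dz
            A[rowx + 1, o_phi + 3 * qq] -= co * dx * dy
            A[rowx + 1, o_phi + 3 * qq + 1] -= co * (diag + dy * dy)
            A[rowx + 1, o_phi + 3 * qq + 2] -= co * dy * dz
            A[rowx + 2, o_phi + 3 * qq] -= co * dx * dz
            A[rowx + 2, o_phi + 3 * qq + 1] -= co * dy * dz
            A[rowx + 2, o_phi + 3 * qq + 2] -= co * (diag + dz * dz)
        b[rowx] = bx
        b[rowx + 1] = by
        b[rowx + 2] = bz

    # ----- closure: force and moment free ------------------------------------
    r2_ = r1 + 3 * Q
    sfx = 0.0
    sfy = 0.0
    smz = 0.0
    for j in range(N):
        A[r2_, o_f + 2 * j] = h
        A[r2_ + 1, o_f + 2 * j + 1] = h
        mrx = Xm[j, 0] - X[0, 0]
        mry = Xm[j, 1] - X[0, 1]
        A[r2_ + 2, o_f + 2 * j] = -h * mry
        A[r2_ + 2, o_f + 2 * j + 1] = h * mrx
        sfx += h * frep[j, 0]
        sfy += h * frep[j, 1]
        smz += h * (mrx * frep[j, 1] - mry * frep[j, 0])
    for p in range(Qf):
        q = nn[p]
        A[r2_, o_phi + 3 * q] += fine_w[p]
        A[r2_ + 1, o_phi + 3 * q + 1] += fine_w[p]
        A[r2_ + 2, o_phi + 3 * q] += -fine_w[p] * (fine[p, 1] - X[0, 1])
        A[r2_ + 2, o_phi + 3 * q + 1] += fine_w[p] * (fine[p, 0] - X[0, 0])
    b[r2_] = -sfx
    b[r2_ + 1] = -sfy
    b[r2_ + 2] = -smz

    u = np.linalg.solve(A, b)

    # ----- switching law at the active joints --------------------------------
    du = np.empty(2 + N + na)
    du[0] = u[0]
    du[1] = u[1]
    for k in range(N):
        du[2 + k] = u[o_th + k]
    for k in range(na):
        kap = (theta[k + 1] - theta[k]) / h
        hp = 0.5 * (1.0 + np.tanh((kc - kap) / delta))
        hm = 0.5 * (1.0 + np.tanh((kc + kap) / delta))
        fp = -(m[k] - 2.0) * hp - 1.0
        fm = -(m[k] + 2.0) * hm + 1.0
        w = 0.5 * (1.0 + np.tanh(m[k] / delta))
        du[2 + N + k] = w * fp + (1.0 - w) * fm
    return du
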