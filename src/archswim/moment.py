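"""The ARCH switching law for the axonemal active moment density.

A fully engaged stretch of dynein activity produces a preferred moment
density; rescaled by it, the active moment density m(s, t) obeys the rate
law

    dm/dt = -(m - 2 sgn(m)) H(kappa_c - sgn(m) kappa) - sgn(m),

with H the Heaviside step.  While the local curvature stays below the
critical threshold (sgn(m) kappa < kappa_c) the engaged equilibria m = +-1
attract; once the threshold is crossed the moment decays at unit rate,
crosses zero, and is captured by the opposite branch -- a hysteretic
relaxation oscillator driven by the local curvature.

Two forms are provided: the exact discontinuous law (:func:`moment_rate`,
the reference for unit tests) and a smoothed variant used inside the stiff
time integrator (:func:`smoothed_moment_rate`).  The smoothed variant blends
the two exact sign branches with a sigmoid weight in m rather than
substituting a sigmoid for sgn() inside the formula: the latter would sweep
the Heaviside argument through +kappa_c as the sigmoid interpolates,
manufacturing a spurious stable equilibrium just above m = 0 that stalls
switching.  The blend converges pointwise to the discontinuous law away
from m = 0 as delta -> 0 and preserves the transversal zero crossing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["moment_rate", "smoothed_switch", "smoothed_step", "smoothed_moment_rate"]


def moment_rate(m, kappa, kappa_c):
    """Exact (discontinuous) ARCH rate dm/dt.

    Parameters
    ----------
    m : array_like
        Active moment density (dimensionless, typically in [-2, 2]).
    kappa : array_like
        Local signed curvature at the same nodes.
    kappa_c : float
        Critical curvature threshold (> 0).

    Returns
    -------
    ndarray or float
        ``-(m - 2 sgn(m)) H(kappa_c - sgn(m) kappa) - sgn(m)`` elementwise,
        with the conventions sgn(0) = 0 and H(0) = 0.
    """
    if kappa_c <= 0:
        raise ValueError("kappa_c must be positive")
    m = np.asarray(m, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(kappa))):
        raise ValueError("non-finite m or kappa")
    sg = np.sign(m)
    # H(0) = 0: attaining the threshold exactly counts as crossed, so the
    # supra-threshold decay dm/dt = -sgn(m) holds for sgn(m) kappa >= kappa_c
    heav = np.where(kappa_c - sg * kappa > 0.0, 1.0, 0.0)
    out = -(m - 2.0 * sg) * heav - sg
    return out if out.ndim else float(out)


def smoothed_switch(x, delta):
    """Odd sigmoid tanh(x/delta) in [-1, 1], converging to sgn as delta -> 0."""
    if delta <= 0:
        raise ValueError("smoothing width delta must be positive")
    return np.tanh(np.asarray(x, dtype=float) / delta)


def smoothed_step(x, delta):
    """Companion smoothed Heaviside (1 + tanh(x/delta)) / 2 in [0, 1]."""
    return 0.5 * (1.0 + smoothed_switch(x, delta))


def smoothed_moment_rate(m, kappa, kappa_c, delta):
    """Smoothed ARCH rate for use inside stiff implicit integration.

    Sigmoid-weighted blend of the two exact sign branches,

        F+ = -(m - 2) H_d(kappa_c - kappa) - 1,
        F- = -(m + 2) H_d(kappa_c + kappa) + 1,
        dm/dt = w(m) F+ + (1 - w(m)) F-,   w = (1 + tanh(m/delta)) / 2,

    with H_d the smoothed step of width delta.  Equals the discontinuous
    law to within O(exp(-|m|/delta)) away from m = 0.
    """
    if kappa_c <= 0:
        raise ValueError("kappa_c must be positive")
    m = np.asarray(m, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    f_plus = -(m - 2.0) * smoothed_step(kappa_c - kappa, delta) - 1.0
    f_minus = -(m + 2.0) * smoothed_step(kappa_c + kappa, delta) + 1.0
    w = smoothed_step(m, delta)
    out = w * f_plus + (1.0 - w) * f_minus
    return out if out.ndim else float(out)
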