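"""Fit simulated curvature profiles to tracked flagellar data.

The fitting statistic is the time-averaged absolute curvature profile
|kappa|(s) over three complete beats.  A library of simulated profiles
(one per dimensionless parameter set) is compared against an experimental
profile by rescaling the simulated arclength with a length parameter
l in [30, 60] um (the simulated curvature converts to 1/um by dividing by
l), interpolating onto the experimental arclength samples truncated at the
tracked length, and accumulating the sum of squared differences.  The
search is an exhaustive grid lookup over (parameter set, l).

The reported error of the best fit is the relative root-sum-square mismatch

    R = sqrt(sum (|k_sim| - |k_exp|)^2) / sqrt(sum |k_sim|^2)

with the summation over the tracked arclength samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FitResult", "error_measure_R", "fit_to_experiment", "default_l_grid"]


def default_l_grid(l_min: float = 30.0, l_max: float = 60.0,
                   spacing: float = 0.5) -> np.ndarray:
    """Length-parameter search grid, default 61 values at 0.5 um spacing."""
    n = int(round((l_max - l_min) / spacing)) + 1
    return np.linspace(l_min, l_max, n)


def error_measure_R(sim_profile, exp_profile) -> float:
    """Relative root-sum-square curvature mismatch on a common sample set."""
    sim = np.abs(np.asarray(sim_profile, dtype=float))
    exp = np.abs(np.asarray(exp_profile, dtype=float))
    if sim.shape != exp.shape:
        raise ValueError("profiles must share their sample set")
    denom = np.sqrt(np.sum(sim**2))
    if denom == 0:
        raise ValueError("simulated profile has zero norm")
    return float(np.sqrt(np.sum((sim - exp) ** 2)) / denom)


@dataclass
class FitResult:
    """Outcome of the grid lookup."""

    best_params: dict          # the dimensionless parameter set of the argmin
    best_l: float              # length scale (um)
    ssd: float                 # sum squared difference at the argmin
    R_bar: float               # relative error of the best fit
    table: pd.DataFrame        # per-candidate best (l, ssd, R)


def fit_to_experiment(exp_s_um, exp_profile, library,
                      l_grid=None) -> FitResult:
    """Grid search of the profile library against an experimental profile.

    Parameters
    ----------
    exp_s_um, exp_profile : array_like
        Experimental arclength samples (um, ascending from 0) and the mean
        |kappa| profile (1/um) at those samples.
    library : iterable of (params_dict, s_grid, profile)
        Simulated profiles on the dimensionless arclength grid ``s_grid``
        in [0, 1]; ``profile`` is dimensionless |kappa|.
    l_grid : array_like, optional
        Candidate flagellar lengths (um); default 30..60 um at 0.5 um.

    Returns
    -------
    FitResult
        Argmin over (candidate, l) of the sum of squared differences,
        with the corresponding relative error R.
    """
    exp_s = np.asarray(exp_s_um, dtype=float)
    exp_k = np.abs(np.asarray(exp_profile, dtype=float))
    if exp_s.ndim != 1 or exp_s.size < 3 or np.any(np.diff(exp_s) <= 0):
        raise ValueError("experimental arclength samples must be ascending")
    if l_grid is None:
        l_grid = default_l_grid()
    l_grid = np.asarray(l_grid, dtype=float)
    L_exp = exp_s[-1]
    usable_l = l_grid[l_grid >= L_exp]
    if usable_l.size == 0:
        raise ValueError(
            f"experimental flagellum ({L_exp:.1f} um) is longer than every "
            f"scaled simulation (max l {l_grid.max():.1f} um)")

    library = list(library)
    if not library:
        raise ValueError("empty profile library")
    rows = []
    best = None
    for params, s_grid, prof in library:
        s_grid = np.asarray(s_grid, dtype=float)
        prof = np.abs(np.asarray(prof, dtype=float))
        cand_best = None
        for l in usable_l:
            # simulated arclength rescaled to micrometres; curvature to 1/um
            sim_at_exp = np.interp(exp_s, s_grid * l, prof / l)
            ssd = float(np.sum((sim_at_exp - exp_k) ** 2))
            if cand_best is None or ssd < cand_best[1]:
                cand_best = (float(l), ssd, error_measure_R(sim_at_exp, exp_k))
        rows.append({**params, "l_um": cand_best[0], "ssd": cand_best[1],
                     "R_bar": cand_best[2]})
        if best is None or cand_best[1] < best[1][1]:
            best = (params, cand_best)
    table = pd.DataFrame(rows).sort_values("ssd").reset_index(drop=True)
    params, (l_best, ssd, rbar) = best
    return FitResult(best_params=dict(params), best_l=l_best, ssd=ssd,
                     R_bar=rbar, table=table)
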