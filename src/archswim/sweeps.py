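"""Parameter sweeps and hysteresis continuation.

:func:`parameter_sweep` runs the steady-beat protocol over a Cartesian grid
of the four dimensionless groups (each point independent and
deterministic); failed points are flagged and kept, never dropped.

:func:`hysteresis_sweep` increments the critical curvature kappa_c along an
ordered path, warm-starting every run from the final state of the previous
one (forward pass), then retraces the path backwards likewise.  Where the
attractor is unique the two passes coincide; inside a bistable window they
separate, which is the hysteresis signature of the switching law.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import run_to_steady_beat, _Discretization
from .analysis import summarize, WaveformSummary
from .params import DimensionlessParameters

__all__ = ["SweepResult", "HysteresisResult", "parameter_sweep", "hysteresis_sweep"]

SWEEP_AXES = ("S", "rho", "M", "kappa_c")


@dataclass
class SweepResult:
    """One summary + convergence flag per grid point."""

    points: list                       # list of dicts with the four groups
    summaries: list                    # WaveformSummary or None per point
    statuses: list                     # "converged" | "no_beat" | "not_converged" | "failed"
    errors: list = field(default_factory=list)

    def to_records(self) -> list:
        recs = []
        for pt, summ, status in zip(self.points, self.summaries, self.statuses):
            rec = {**pt, "status": status}
            if summ is not None:
                rec["summary"] = summ.to_dict()
            recs.append(rec)
        return recs

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1))

    def profile_library(self) -> list:
        """(params, s_grid, mean |kappa| profile) triples for profile fitting.

        Failed and quiescent grid points are skipped (they carry no beat
        profile to compare against).
        """
        out = []
        for pt, summ, status in zip(self.points, self.summaries, self.statuses):
            if summ is None or status == "no_beat" or summ.n_beats < 1:
                continue
            out.append((pt, summ.s_grid, summ.mean_abs_curv))
        return out


def parameter_sweep(grid: dict, base: DimensionlessParameters,
                    out_dir: str | Path | None = None) -> SweepResult:
    """Run the steady-beat protocol at every point of a Cartesian grid.

    ``grid`` maps any subset of ``("S", "rho", "M", "kappa_c")`` to value
    lists; remaining groups stay at their ``base`` values.  Summaries are
    persisted incrementally as JSON when ``out_dir`` is given.
    """
    axes = [(k, list(np.atleast_1d(grid[k]))) for k in SWEEP_AXES if k in grid]
    unknown = set(grid) - set(SWEEP_AXES)
    if unknown:
        raise ValueError(f"unknown sweep axes: {sorted(unknown)}")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    result = SweepResult(points=[], summaries=[], statuses=[], errors=[])
    for combo in itertools.product(*[v for _, v in axes]):
        pt = {k: float(v) for (k, _), v in zip(axes, combo)}
        params = base.with_(**pt)
        try:
            record, status, _period = run_to_steady_beat(params)
            summ = summarize(record)
            err = ""
        except Exception as exc:  # keep the grid point, flag the failure
            summ, status, err = None, "failed", repr(exc)
        result.points.append(pt)
        result.summaries.append(summ)
        result.statuses.append(status)
        result.errors.append(err)
        if out_dir is not None:
            tag = "_".join(f"{k}{v:g}" for k, v in pt.items())
            rec = {**pt, "status": status, "error": err}
            if summ is not None:
                rec["summary"] = summ.to_dict()
            (out_dir / f"point_{tag}.json").write_text(json.dumps(rec, indent=1))
    return result


@dataclass
class HysteresisResult:
    """Paired velocity curves from the forward and backward kappa_c passes."""

    kc_values: np.ndarray
    forward_velocity: np.ndarray
    backward_velocity: np.ndarray
    forward_summaries: list
    backward_summaries: list
    forward_status: list
    backward_status: list

    @property
    def max_gap(self) -> float:
        """Largest |forward - backward| velocity difference along the path."""
        return float(np.max(np.abs(self.forward_velocity - self.backward_velocity)))

    def to_dict(self) -> dict:
        return {
            "kc_values": self.kc_values.tolist(),
            "forward_velocity": self.forward_velocity.tolist(),
            "backward_velocity": self.backward_velocity.tolist(),
            "forward_status": self.forward_status,
            "backward_status": self.backward_status,
        }


def hysteresis_sweep(kc_values, base: DimensionlessParameters,
                     direction: str = "both") -> HysteresisResult:
    """Warm-started continuation of the steady beat in kappa_c.

    The forward pass visits ``kc_values`` in order, initializing each run
    from the previous converged final state (the first point cold-starts
    from the parabola); the backward pass retraces in reverse, warm-started
    from the forward end state.  Non-convergence at a step propagates the
    last converged state onward with a flag.
    """
    kc_values = np.asarray(kc_values, dtype=float)
    if kc_values.ndim != 1 or kc_values.size < 2:
        raise ValueError("need an ordered path of at least 2 kappa_c values")
    disc = _Discretization(base)

    def _steady_velocity(record):
        # velocity of the settled beat: average |dX0| per beat over the last
        # three complete beats (an all-beat average would fold the cold-start
        # transient into the first path point and fake an endpoint gap)
        from .analysis import swimming_velocity, segment_beats
        b = segment_beats(record)
        if b.size < 2:
            return 0.0
        return swimming_velocity(record, b[-min(4, b.size):])

    def _pass(values, state0):
        vel, summs, stats = [], [], []
        state = state0
        for kc in values:
            params = base.with_(kappa_c=float(kc))
            record, status, _ = run_to_steady_beat(params, state0=state, disc=disc)
            summ = summarize(record)
            if status != "not_converged" or summ.n_beats >= 1:
                state = record.state_at(len(record.times) - 1)
                state.time = 0.0
            vel.append(_steady_velocity(record))
            summs.append(summ)
            stats.append(status)
        return np.array(vel), summs, stats, state

    fwd_v, fwd_s, fwd_st, end_state = _pass(kc_values, None)
    if direction == "forward":
        bwd_v, bwd_s, bwd_st = fwd_v[::-1].copy(), fwd_s[::-1], fwd_st[::-1]
    else:
        bwd_v, bwd_s, bwd_st, _ = _pass(kc_values[::-1], end_state)
        bwd_v, bwd_s, bwd_st = bwd_v[::-1], bwd_s[::-1], bwd_st[::-1]
    return HysteresisResult(
        kc_values=kc_values, forward_velocity=fwd_v, backward_velocity=bwd_v,
        forward_summaries=fwd_s, backward_summaries=bwd_s,
        forward_status=fwd_st, backward_status=bwd_st)
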