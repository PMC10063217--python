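"""Waveform analytics: beat segmentation and summary statistics.

A *beat* is delimited by a Poincare section on the proximal tangent angle
theta(0, t): rising zero crossings of the signal minus its running mean,
with crossing times linearly interpolated.  From the segmented record we
compute swimming velocity in cell lengths per beat, the dimensionless beat
frequency, the time-averaged absolute curvature profile |kappa|(s) over
complete beats (the fitting statistic), the head-yaw amplitude, and a
qualitative mode label (penetrative / activated / hyperactivated /
nonprogressive / no_beat).  The labels mirror the standard human-sperm
motility modes: low-yaw progressive, high-yaw progressive, and
high-curvature nonprogressive; thresholds are configurable since the
distinction is conventionally drawn by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "WaveformSummary",
    "ClassificationThresholds",
    "segment_beats",
    "beat_profiles",
    "swimming_velocity",
    "beat_frequency",
    "mean_abs_curvature",
    "yaw_amplitude",
    "wave_direction",
    "classify_waveform",
    "summarize",
]


@dataclass
class ClassificationThresholds:
    """Configurable thresholds for the qualitative mode label."""

    no_beat_amplitude: float = 1e-3       # rad, floor on theta(0,t) oscillation
    progressive_velocity: float = 0.01    # cell lengths per beat
    penetrative_yaw: float = 0.6          # rad, half peak-to-peak head yaw
    hyperactivated_curvature: float = 25.0  # dimensionless peak |kappa|


@dataclass
class WaveformSummary:
    """Per-run summary quantities of a (steady) beat."""

    velocity: float                       # cell lengths per beat
    frequency: float                      # beats per unit dimensionless time
    mean_abs_curv: np.ndarray             # profile vs arclength
    s_grid: np.ndarray
    yaw_amplitude: float                  # rad, half peak-to-peak of theta(0,t)
    amplitude: float                      # same signal, used for the beat floor
    label: str = ""
    n_beats: int = 0
    peak_curvature: float = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_abs_curv"] = np.asarray(self.mean_abs_curv).tolist()
        d["s_grid"] = np.asarray(self.s_grid).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WaveformSummary":
        d = dict(d)
        d["mean_abs_curv"] = np.asarray(d["mean_abs_curv"], dtype=float)
        d["s_grid"] = np.asarray(d["s_grid"], dtype=float)
        return cls(**d)


def _section_signal(times: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Signal minus its running mean (window of ~the full span / 4)."""
    n = signal.size
    w = max(5, n // 8)
    kernel = np.ones(w) / w
    # odd reflection continues oscillations across the ends without biasing
    # the running mean (a constant pad would drag crossings near the edges)
    left = 2 * signal[0] - signal[1:w // 2 + 1][::-1]
    right = 2 * signal[-1] - signal[-(w - w // 2):-1][::-1]
    pad = np.concatenate([left, signal, right])
    running = np.convolve(pad, kernel, mode="valid")
    return signal - running


def segment_beats(record_or_times, signal: np.ndarray | None = None) -> np.ndarray:
    """Beat boundary times: rising zero crossings of the detrended proximal
    tangent angle, linearly interpolated.

    Accepts either a BeatRecord (uses theta(0, t)) or (times, signal)
    arrays.  Returns an array of crossing times (possibly empty).
    """
    if signal is None:
        times = np.asarray(record_or_times.times)
        sig = record_or_times.theta[:, 0]
    else:
        times = np.asarray(record_or_times, dtype=float)
        sig = np.asarray(signal, dtype=float)
    if times.size < 4:
        return np.empty(0)
    y = _section_signal(times, sig)
    # ignore numerically flat signals
    if np.max(np.abs(y)) < 1e-12:
        return np.empty(0)
    up = (y[:-1] < 0) & (y[1:] >= 0)
    idx = np.flatnonzero(up)
    if idx.size == 0:
        return np.empty(0)
    # hysteresis: count a crossing only after the signal has dipped below
    # -thr since the previous counted crossing (debounces noise wiggles)
    thr = 0.25 * np.percentile(np.abs(y), 90)
    armed = np.concatenate([[0], np.cumsum(y < -thr)])
    kept = []
    last_armed = 0
    for i in idx:
        if armed[i + 1] > last_armed:
            kept.append(i)
            last_armed = armed[i + 1]
    if not kept:
        return np.empty(0)
    idx = np.asarray(kept)
    t0, t1 = times[idx], times[idx + 1]
    y0, y1 = y[idx], y[idx + 1]
    return t0 + (t1 - t0) * (-y0) / (y1 - y0)


def _complete_beats(boundaries: np.ndarray):
    return [(boundaries[i], boundaries[i + 1]) for i in range(boundaries.size - 1)]


def swimming_velocity(record, boundaries: np.ndarray | None = None) -> float:
    """Progressive speed in cell lengths per beat.

    Base displacement |X0(end of beat) - X0(start of beat)| averaged over
    complete beats, normalized by the cell length.  Returns 0.0 when no
    complete beat exists.
    """
    if boundaries is None:
        boundaries = segment_beats(record)
    if boundaries.size < 2:
        return 0.0
    t = record.times
    disp = []
    for ta, tb in _complete_beats(boundaries):
        Xa = np.array([np.interp(ta, t, record.X0[:, k]) for k in range(2)])
        Xb = np.array([np.interp(tb, t, record.X0[:, k]) for k in range(2)])
        disp.append(np.linalg.norm(Xb - Xa))
    return float(np.mean(disp) / record.params.cell_length)


def beat_frequency(record, boundaries: np.ndarray | None = None) -> float:
    """Beats per unit dimensionless time (reciprocal mean beat interval)."""
    if boundaries is None:
        boundaries = segment_beats(record)
    if boundaries.size < 2:
        raise ValueError("need at least 2 beat boundaries for a frequency")
    return float(1.0 / np.mean(np.diff(boundaries)))


def beat_profiles(record, boundaries: np.ndarray | None = None) -> list[np.ndarray]:
    """Per-beat time-averages of |kappa(s, t)|, one profile per complete beat."""
    if boundaries is None:
        boundaries = segment_beats(record)
    kap = np.abs(record.curvature())
    t = record.times
    out = []
    for ta, tb in _complete_beats(boundaries):
        sel = (t >= ta) & (t <= tb)
        if np.count_nonzero(sel) < 2:
            continue
        out.append(np.trapezoid(kap[sel], t[sel], axis=0) / (t[sel][-1] - t[sel][0]))
    return out


def mean_abs_curvature(record, n_beats: int = 3,
                       boundaries: np.ndarray | None = None) -> np.ndarray:
    """Time average of |kappa(s, t)| over the last ``n_beats`` complete beats."""
    if boundaries is None:
        boundaries = segment_beats(record)
    if boundaries.size < n_beats + 1:
        raise ValueError(f"need at least {n_beats} complete beats, "
                         f"found {max(boundaries.size - 1, 0)}")
    ta, tb = boundaries[-1 - n_beats], boundaries[-1]
    t = record.times
    sel = (t >= ta) & (t <= tb)
    kap = np.abs(record.curvature()[sel])
    return np.trapezoid(kap, t[sel], axis=0) / (t[sel][-1] - t[sel][0])


def wave_direction(record, boundaries: np.ndarray | None = None,
                   s_range: tuple = (0.15, 0.7)) -> str:
    """Propagation direction of the curvature wave.

    Extracts the phase of the fundamental beat harmonic of kappa(s, t) at
    each arclength and fits its slope over ``s_range``: a wave
    cos(omega t - k s) with k > 0 has phase decreasing in s, i.e.
    ``anterograde`` (base-to-tip) propagation.
    """
    if boundaries is None:
        boundaries = segment_beats(record)
    if boundaries.size < 3:
        return "undetermined"
    t = record.times
    sel = (t >= boundaries[-3]) & (t <= boundaries[-1])
    tt = t[sel]
    period = 0.5 * (boundaries[-1] - boundaries[-3])
    k = record.curvature()[sel]
    s = record.s_curvature
    span = (s >= s_range[0]) & (s <= s_range[1])
    omega = 2.0 * np.pi / period
    e = np.exp(-1j * omega * tt)
    coef = np.trapezoid(e[:, None] * (k - k.mean(axis=0)), tt, axis=0)
    phase = np.unwrap(np.angle(coef[span]))
    slope = np.polyfit(s[span], phase, 1)[0]
    return "anterograde" if slope < 0 else "retrograde"


def yaw_amplitude(record, boundaries: np.ndarray | None = None) -> float:
    """Half peak-to-peak oscillation of the head angle theta(0, t) over the
    analysed span (last three beats when available)."""
    if boundaries is None:
        boundaries = segment_beats(record)
    t = record.times
    sig = record.theta[:, 0]
    if boundaries.size >= 4:
        sel = (t >= boundaries[-4]) & (t <= boundaries[-1])
        sig = sig[sel]
    y = sig - np.mean(sig)
    return float(0.5 * (np.max(y) - np.min(y)))


def classify_waveform(summary: WaveformSummary,
                      thresholds: ClassificationThresholds | None = None) -> str:
    """Assign a qualitative motility-mode label from a summary alone.

    ``no_beat`` below the amplitude floor; nonprogressive oscillation with
    high curvature is ``hyperactivated`` (``nonprogressive`` otherwise);
    progressive runs split into ``penetrative`` (low yaw) and ``activated``
    (high yaw).
    """
    th = thresholds or ClassificationThresholds()
    if summary.amplitude < th.no_beat_amplitude or summary.n_beats < 1:
        return "no_beat"
    if summary.velocity < th.progressive_velocity:
        # high-curvature nonprogressive beating = hyperactivated archetype
        if summary.peak_curvature >= th.hyperactivated_curvature:
            return "hyperactivated"
        return "nonprogressive"
    return "penetrative" if summary.yaw_amplitude < th.penetrative_yaw else "activated"


def summarize(record, n_beats: int = 3,
              thresholds: ClassificationThresholds | None = None) -> WaveformSummary:
    """Full summary of a record: velocity, frequency, curvature profile,
    yaw amplitude and mode label."""
    boundaries = segment_beats(record)
    t = record.times
    sig = record.theta[:, 0]
    tail = t >= t[-1] - 0.5 * (t[-1] - t[0])
    amp = float(0.5 * (np.max(sig[tail]) - np.min(sig[tail])))
    n_complete = max(boundaries.size - 1, 0)
    if n_complete >= 1:
        vel = swimming_velocity(record, boundaries)
        freq = beat_frequency(record, boundaries) if n_complete >= 2 else 0.0
        kprof = (mean_abs_curvature(record, n_beats, boundaries)
                 if n_complete >= n_beats else
                 np.mean(np.abs(record.curvature()[t >= boundaries[0]]), axis=0))
        yaw = yaw_amplitude(record, boundaries)
        peak = float(np.max(np.abs(record.curvature()[t >= boundaries[0]])))
    else:
        vel, freq, yaw = 0.0, 0.0, 0.0
        kprof = np.mean(np.abs(record.curvature()), axis=0)
        peak = float(np.max(np.abs(record.curvature())))
    summary = WaveformSummary(
        velocity=vel, frequency=freq, mean_abs_curv=kprof,
        s_grid=record.s_curvature, yaw_amplitude=yaw, amplitude=amp,
        n_beats=n_complete, peak_curvature=peak)
    summary.label = classify_waveform(summary, thresholds)
    return summary
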