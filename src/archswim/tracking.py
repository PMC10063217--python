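"""Tracked flagellar centerlines: file schema, curvature analysis, synthesis.

Tracked waveforms are frames of ordered 2D centerline points (proximal to
distal, micrometres) at increasing timestamps, as exported by flagellar
tracking software.  The on-disk schema is a plain CSV dialect with header
``frame,time_s,point_id,x_um,y_um`` (comma-separated, UTF-8).

The experimental analogue of the simulator's curvature statistic is
computed per frame from a cubic-spline fit of the centerline: signed planar
curvature from the spline derivatives, beats delimited with the same
Poincare machinery applied to the proximal tangent angle, and |kappa|
averaged over three complete beats on a common arclength grid.

:func:`generate_synthetic_track` turns a simulated beat record into a
synthetic tracked waveform (fixed frame rate, positional noise, truncated
distal end) emulating the limitations of real imaging -- the distal tip is
hard to image and is routinely lost by trackers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.signal import savgol_filter

__all__ = [
    "TrackedWaveform",
    "read_tracked_waveform",
    "write_tracked_waveform",
    "frame_curvature",
    "experimental_mean_abs_curvature",
    "generate_synthetic_track",
]

CSV_COLUMNS = ["frame", "time_s", "point_id", "x_um", "y_um"]


@dataclass
class TrackedWaveform:
    """Frames of ordered 2D flagellar centerline points with timestamps."""

    frames: np.ndarray            # (nf,) int frame indices
    times: np.ndarray             # (nf,) seconds, strictly increasing
    points: list                  # nf arrays of shape (n_pts_i, 2), micrometres
    undersampled: bool = False    # set by the generator on low frame rates

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.points) != self.frames.size or self.frames.size != self.times.size:
            raise ValueError("frames, times and points must align")
        if self.frames.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.size

    def arclengths(self) -> np.ndarray:
        """Polyline length of each frame (micrometres)."""
        return np.array([np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))
                         for p in self.points])

    @property
    def tracked_length(self) -> float:
        """Shortest per-frame polyline length: the usable common arclength."""
        return float(np.min(self.arclengths()))


def read_tracked_waveform(path: str | Path) -> TrackedWaveform:
    """Read and validate a tracked-waveform CSV.

    Points must be ordered proximal-to-distal (contiguous ``point_id`` from
    0) within each frame, and frame timestamps strictly increasing.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracked-waveform file missing columns: {missing}")
    frames, times, points = [], [], []
    for fr, grp in df.groupby("frame", sort=True):
        pid = grp["point_id"].to_numpy()
        if not np.array_equal(pid, np.arange(pid.size)):
            raise ValueError(f"frame {fr}: point_id must run 0..{pid.size - 1} in order")
        t = grp["time_s"].to_numpy()
        if np.ptp(t) > 1e-12:
            raise ValueError(f"frame {fr}: inconsistent timestamps within frame")
        frames.append(int(fr))
        times.append(float(t[0]))
        points.append(grp[["x_um", "y_um"]].to_numpy(dtype=float))
    tw = TrackedWaveform(frames=np.array(frames), times=np.array(times), points=points)
    return tw


def write_tracked_waveform(tw: TrackedWaveform, path: str | Path) -> None:
    """Serialize to the CSV schema (lossless round trip to ~1e-9 um)."""
    rows = []
    for fr, t, pts in zip(tw.frames, tw.times, tw.points):
        for pid, (x, y) in enumerate(pts):
            rows.append((fr, t, pid, x, y))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def _frame_spline(pts: np.ndarray):
    """Arclength-parameterized interpolating splines (x(s), y(s))."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("degenerate (duplicated) centerline points")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return CubicSpline(s, pts[:, 0]), CubicSpline(s, pts[:, 1]), s[-1]


def _frame_angle_spline(pts: np.ndarray, smooth: bool = False):
    """Cubic spline of the tangent angle theta(s) of one frame.

    The angle is measured on the chords between consecutive tracked points
    (at the chord midpoints) and unwrapped; curvature then needs only ONE
    differentiation, which is far better conditioned on noisy points than
    the second derivative of the position splines.  With ``smooth=True`` a
    generalized-cross-validated smoothing spline is fit instead of an
    interpolant.
    """
    d = np.diff(pts, axis=0)
    seg = np.linalg.norm(d, axis=1)
    if np.any(seg <= 0):
        raise ValueError("degenerate (duplicated) centerline points")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_mid = 0.5 * (s[:-1] + s[1:])
    ang = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    if smooth:
        return make_smoothing_spline(s_mid, ang), s[-1]
    return CubicSpline(s_mid, ang), s[-1]


def frame_curvature(pts: np.ndarray, s_eval: np.ndarray,
                    smooth: bool = False) -> np.ndarray:
    """Signed planar curvature kappa = d theta/ds of one frame at ``s_eval``.

    theta is the chord tangent angle spline of the frame (optionally GCV
    smoothed); positive = counterclockwise turning of the tangent.
    """
    sp, _ = _frame_angle_spline(pts, smooth=smooth)
    return sp(s_eval, 1)


def proximal_angle_signal(tw: TrackedWaveform) -> np.ndarray:
    """Tangent angle at the proximal end of each frame (unwrapped, rad)."""
    ang = [np.arctan2(pts[1, 1] - pts[0, 1], pts[1, 0] - pts[0, 0])
           for pts in tw.points]
    return np.unwrap(np.asarray(ang))


def experimental_mean_abs_curvature(tw: TrackedWaveform, n_beats: int = 3,
                                    n_samples: int = 101,
                                    smooth: bool = True):
    """Mean |kappa| profile over ``n_beats`` complete beats, in 1/um.

    Beats are delimited by the Poincare section on the proximal tangent
    angle.  Per-frame curvature is the derivative of the chord tangent
    angle spline, GCV-smoothed in arclength by default, and the signed
    curvature is additionally low-passed across frames (Savitzky-Golay,
    quadratic, ~quarter-beat window) before rectification -- localization noise is
    zero-mean in kappa but biases |kappa| upward if rectified raw
    (``smooth=False`` disables both).  Returns (s_grid_um, profile) on the
    common arclength grid truncated at the shortest tracked frame, keeping
    one point-spacing clear of the spline ends.
    """
    from .analysis import segment_beats

    if tw.n_frames < 8:
        raise ValueError("too few frames for beat segmentation")
    sig = proximal_angle_signal(tw)
    boundaries = segment_beats(tw.times, sig)
    if boundaries.size < n_beats + 1:
        raise ValueError(f"need at least {n_beats} complete beats, found "
                         f"{max(boundaries.size - 1, 0)}")
    # temporal low-pass of the tracked point coordinates (Savitzky-Golay,
    # quadratic, ~quarter-beat window): localization noise is independent
    # across frames while the waveform moves smoothly; possible only when
    # the tracker reports the same point set in every frame
    period_frames = np.mean(np.diff(boundaries)) / np.mean(np.diff(tw.times))
    w_t = int(np.clip(round(period_frames / 4), 5, 11)) | 1
    counts = {len(p) for p in tw.points}
    if smooth and len(counts) == 1 and tw.n_frames > w_t + 2:
        P = savgol_filter(np.stack(tw.points), w_t, 2, axis=0)
        tw = TrackedWaveform(frames=tw.frames, times=tw.times, points=list(P),
                             undersampled=tw.undersampled)
    ta, tb = boundaries[-1 - n_beats], boundaries[-1]
    sel = (tw.times >= ta) & (tw.times <= tb)
    L = tw.tracked_length
    # keep one point-spacing clear of the spline support ends, where the
    # boundary conditions distort the second derivative
    edge = L / (min(len(p) for p in tw.points) - 1)
    s_grid = np.linspace(edge, L - edge, n_samples)
    kaps = np.array([frame_curvature(tw.points[i], s_grid, smooth=smooth)
                     for i in np.flatnonzero(sel)])
    if smooth and kaps.shape[0] > w_t + 2:
        kaps = savgol_filter(kaps, w_t, 2, axis=0)
    kaps = np.abs(kaps)
    t_sel = tw.times[sel]
    profile = np.trapezoid(kaps, t_sel, axis=0) / (t_sel[-1] - t_sel[0])
    return s_grid, profile


def generate_synthetic_track(record, L_um: float = 55.0,
                             frame_rate_hz: float = 200.0,
                             noise_um: float = 0.0,
                             truncate_frac: float = 0.0,
                             seed: int = 0,
                             beat_hz: float = 10.0,
                             n_points: int | None = None,
                             duration_beats: float | None = None) -> TrackedWaveform:
    """Emulate a tracked imaging experiment from a simulated beat record.

    The record's mean beat period is mapped to ``1 / beat_hz`` seconds of
    real time; the centerline is sampled at ``frame_rate_hz``, scaled to a
    flagellum of ``L_um`` micrometres, truncated by ``truncate_frac`` of the
    distal arclength, and perturbed with i.i.d. Gaussian positional noise of
    standard deviation ``noise_um``.  Deterministic for a fixed seed.
    """
    from .analysis import segment_beats
    from .filament import reconstruct_positions, FlagellumShape

    if L_um <= 0 or frame_rate_hz <= 0 or beat_hz <= 0:
        raise ValueError("scales must be positive")
    if not (0 <= truncate_frac < 1):
        raise ValueError("truncate_frac must lie in [0, 1)")
    boundaries = segment_beats(record)
    if boundaries.size < 2:
        raise ValueError("record carries no complete beat to synthesize from")
    period = float(np.mean(np.diff(boundaries)))
    undersampled = frame_rate_hz / beat_hz < 10
    # dimensionless time per real second
    rate = period * beat_hz
    n_avail = boundaries[-1] - boundaries[0]
    span_beats = duration_beats if duration_beats is not None else n_avail / period
    t_start = boundaries[0]
    n_frames = int(np.floor(span_beats * period / rate * frame_rate_hz)) + 1
    t_frames_s = np.arange(n_frames) / frame_rate_hz
    t_dimless = t_start + t_frames_s * rate

    rng = np.random.default_rng(seed)
    # sample the centerline at its own joints (plus the exact truncation
    # endpoint): the simulated shape is a polyline, and samples placed
    # inside segments would make the spline trace the kinks instead of the
    # waveform; explicit n_points below the joint count subsamples evenly
    n_joints = record.theta.shape[1] + 1
    s_end = 1.0 - truncate_frac
    joints = np.linspace(0.0, 1.0, n_joints)
    s_keep = joints[joints <= s_end + 1e-12]
    if not np.isclose(s_keep[-1], s_end):
        s_keep = np.append(s_keep, s_end)
    if n_points is not None and n_points < s_keep.size:
        s_keep = s_keep[np.unique(np.linspace(0, s_keep.size - 1, n_points)
                                  .round().astype(int))]
    s_nodes = record.s_nodes
    frames, pts_list = [], []
    for k, td in enumerate(t_dimless):
        theta = np.array([np.interp(td, record.times, record.theta[:, j])
                          for j in range(record.theta.shape[1])])
        X0 = np.array([np.interp(td, record.times, record.X0[:, j]) for j in range(2)])
        X = reconstruct_positions(FlagellumShape(theta=theta, X0=X0))
        xk = np.interp(s_keep, s_nodes, X[:, 0])
        yk = np.interp(s_keep, s_nodes, X[:, 1])
        pts = np.column_stack([xk, yk]) * L_um
        pts += rng.normal(0.0, noise_um, size=pts.shape) if noise_um > 0 else 0.0
        frames.append(k)
        pts_list.append(pts)
    return TrackedWaveform(frames=np.array(frames), times=t_frames_s,
                           points=pts_list, undersampled=undersampled)
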