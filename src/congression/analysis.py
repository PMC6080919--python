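"""Trajectory segmentation: capture-event detection and phase statistics.

Chromosome trajectories show two phases: slow advective/diffusive motion
while embedded in the contracting F-actin network, then fast directed
poleward transport along microtubules after capture. A capture event is
the transition point between the two, identified as a time point followed
by at least four subsequent steps of unidirectional, fast, poleward
motion — or at least two such steps if the overall direction of motion
reverses at that point.

A step qualifies when its instantaneous speed is at or above the fast
threshold, the angle to the previous displacement is at most the angle
threshold, and its radial velocity component relative to the animal pole
is negative (poleward). Phase speeds are estimated from displacements
over a multi-frame window, which suppresses the upward bias that
frame-to-frame localization noise adds to instantaneous speeds; the
near-stationary plateau after arrival at the spindle is trimmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "DetectionThresholds",
    "CaptureEvent",
    "CaptureStatistics",
    "distance_to_ap",
    "detect_capture_event",
    "phase_speeds",
    "capture_statistics",
    "analyze_trajectories",
]


@dataclass(frozen=True)
class DetectionThresholds:
    """Tunable criteria for capture-event detection.

    ``fast_speed`` (µm/min) separates F-actin-driven motion (at most
    ~2 µm/min per 30 µm of start distance, i.e. < 5 µm/min anywhere in a
    70-µm nucleus) from the ~9 µm/min microtubule transport.
    """

    fast_speed: float = 5.0          # µm/min
    max_angle_deg: float = 60.0      # between consecutive displacement vectors
    run_fast: int = 4                # qualifying steps for the plain rule
    run_turn: int = 2                # qualifying steps when a direction reversal coincides
    step_smooth_window: int = 1      # frames; 1 = classify raw frame-to-frame steps
    smooth_window: int = 5           # frames, moving average for the overall direction
    turn_tolerance: int = 2          # frames between reversal and run start
    speed_window: int = 5            # frames per displacement window for phase speeds
    pre_speed_factor: float = 1.5    # run net speed must exceed this times the pre-phase speed
    arrival_speed: float = 1.0       # µm/min, below this near the pole = arrived
    arrival_distance: float = 8.0    # µm from the AP; covers arrival at either centrosome


@dataclass(frozen=True)
class CaptureEvent:
    """Detected transition from slow to fast poleward motion."""

    chromosome: int | None
    time_min: float
    frame_index: int
    rule: str                        # "four-step" or "two-step+turn"
    pre_speed: float | None          # µm/min, None at the trajectory edge
    post_speed: float | None


def distance_to_ap(times_s, positions, p) -> pd.DataFrame:
    """Euclidean distance of each frame position to the AP point ``p``.

    Returns a DataFrame with columns ``t_min`` and ``distance_um``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3 or positions.shape[0] == 0:
        raise ValidationError("positions must be a non-empty (n, 3) array")
    d = np.linalg.norm(positions - np.asarray(p, dtype=float), axis=1)
    return pd.DataFrame({"t_min": np.asarray(times_s, dtype=float) / 60.0, "distance_um": d})


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0, edges averaged over the
    available part of the window."""
    n = x.shape[0]
    kernel = np.ones(window)
    if x.ndim == 1:
        s = np.convolve(x, kernel, mode="same")
        c = np.convolve(np.ones(n), kernel, mode="same")
        return s / c
    out = np.empty_like(x, dtype=float)
    c = np.convolve(np.ones(n), kernel, mode="same")
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], kernel, mode="same") / c
    return out


def _qualifying_steps(times_s, xyz, p, thr: DetectionThresholds):
    """Boolean per-step mask: fast, unidirectional and poleward.

    Steps are classified on lightly smoothed positions
    (``step_smooth_window``-frame moving average) so that frame-to-frame
    localization noise does not break genuine transport runs; the run
    rules and thresholds then apply to these smoothed steps.
    """
    if thr.step_smooth_window > 1:
        xyz = _moving_average(xyz, thr.step_smooth_window)
    disp = np.diff(xyz, axis=0)
    dt = np.diff(times_s)
    if np.any(dt <= 0):
        raise ValidationError("frame times must be strictly increasing")
    norms = np.linalg.norm(disp, axis=1)
    speed = norms / dt * 60.0  # µm/min
    d = np.linalg.norm(xyz - p, axis=1)
    poleward = np.diff(d) < 0.0

    cos_thr = np.cos(np.deg2rad(thr.max_angle_deg))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", disp[:-1], disp[1:]) / (norms[:-1] * norms[1:])
    straight = np.zeros(len(disp), dtype=bool)
    straight[1:] = np.nan_to_num(cosang, nan=-1.0) >= cos_thr

    fast_poleward = (speed >= thr.fast_speed) & poleward
    return fast_poleward & straight, fast_poleward


def _refine_knee(times_s: np.ndarray, d: np.ndarray, idx: int, thr: DetectionThresholds) -> int:
    """Two-segment change-point fit of distance-to-AP around ``idx``.

    The transition from slow advective/diffusive approach to microtubule
    transport is a sharp slope change in d(t); the least-squares
    breakpoint localizes it to about one frame even when per-step
    classification is delayed by localization noise.
    """
    half = 4 * thr.run_fast
    lo = max(0, idx - half)
    hi = min(len(d) - 1, idx + half)
    near_pole = np.nonzero(d[idx:hi + 1] < 3.0)[0]
    if near_pole.size:
        hi = idx + int(near_pole[0])
    if hi - lo < 6:
        return idx
    t = times_s[lo : hi + 1]
    y = d[lo : hi + 1]
    best, best_sse = idx, np.inf
    for b in range(2, len(y) - 2):
        sse = 0.0
        for ts, ys in ((t[: b + 1], y[: b + 1]), (t[b:], y[b:])):
            coef = np.polyfit(ts, ys, 1)
            resid = ys - np.polyval(coef, ts)
            sse += float(resid @ resid)
        if sse < best_sse:
            best_sse, best = sse, lo + b
    return best


def _run_starts(mask: np.ndarray, run: int) -> np.ndarray:
    """Indices i where mask[i:i+run] are all True."""
    if run > mask.size:
        return np.array([], dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(mask, run)
    return np.nonzero(windows.all(axis=1))[0]


def _turn_frames(times_s, xyz, thr: DetectionThresholds) -> np.ndarray:
    """Frames where the smoothed overall direction of motion reverses."""
    smoothed = _moving_average(xyz, thr.smooth_window)
    w = thr.smooth_window
    n = xyz.shape[0]
    turns = []
    for i in range(w, n - w):
        before = smoothed[i] - smoothed[i - w]
        after = smoothed[i + w] - smoothed[i]
        nb, na = np.linalg.norm(before), np.linalg.norm(after)
        if nb == 0 or na == 0:
            continue
        if np.dot(before, after) / (nb * na) < 0.0:  # > 90 degrees
            turns.append(i)
    return np.array(turns, dtype=int)


def detect_capture_event(
    times_s,
    positions,
    p,
    thresholds: DetectionThresholds | None = None,
    chromosome: int | None = None,
) -> CaptureEvent | None:
    """Detect the microtubule-capture event in one trajectory.

    ``times_s`` are frame times in seconds, ``positions`` an (n, 3) array
    in µm, ``p`` the AP point. Returns the earliest qualifying event, or
    None when the trajectory contains no fast directed poleward phase.
    Trajectories shorter than six frames yield None with a warning.
    """
    thr = thresholds or DetectionThresholds()
    times_s = np.asarray(times_s, dtype=float)
    xyz = np.atleast_2d(np.asarray(positions, dtype=float))
    p = np.asarray(p, dtype=float)
    if xyz.shape[0] < 6:
        warnings.warn("trajectory shorter than six frames; capture detection skipped")
        return None

    qual, fast_poleward = _qualifying_steps(times_s, xyz, p, thr)
    d = np.linalg.norm(xyz - p, axis=1)
    n = xyz.shape[0]

    # windowed speeds for the pre-phase estimate used by net_ok
    w = thr.speed_window
    wspeed = np.array([])
    if n > w:
        i_all = np.arange(n - w)
        wspeed = (
            np.linalg.norm(xyz[i_all + w] - xyz[i_all], axis=1)
            / (times_s[i_all + w] - times_s[i_all]) * 60.0
        )

    def net_ok(i: int) -> bool:
        # The run as a whole must be fast and poleward: per-step noise can
        # pass the step thresholds by chance but cancels in the net motion.
        # It must also clearly exceed the track's own pre-phase speed —
        # a capture event is a transition to *faster* motion, and the
        # advective phase of distal chromosomes can approach the absolute
        # fast threshold on its own.
        j = min(i + 2 * thr.run_fast + 4, n - 1)
        # truncate the span where the track reaches the pole, so short
        # transport phases ending at the AP are not diluted by the
        # stationary arrival plateau
        near = np.nonzero(d[i + 1 : j + 1] < 3.0)[0]
        if near.size:
            j = i + 1 + int(near[0])
        if j <= i:
            return False
        net_speed = np.linalg.norm(xyz[j] - xyz[i]) / (times_s[j] - times_s[i]) * 60.0
        floor = thr.fast_speed
        if i > w and wspeed.size:
            pre = float(np.median(wspeed[: i - w])) if i - w > 0 else None
            if pre is not None:
                floor = max(floor, thr.pre_speed_factor * pre)
        return net_speed >= floor and d[j] < d[i]

    candidates: list[tuple[int, str]] = []
    for i in _run_starts(qual, thr.run_fast):
        if net_ok(int(i)):
            candidates.append((int(i), "four-step"))
            break
    starts_b = _run_starts(qual, thr.run_turn)
    if starts_b.size:
        turns = _turn_frames(times_s, xyz, thr)
        for i in starts_b:
            if (
                turns.size
                and np.min(np.abs(turns - i)) <= thr.turn_tolerance
                and net_ok(int(i))
            ):
                candidates.append((int(i), "two-step+turn"))
                break

    if not candidates:
        return None
    idx, rule = min(candidates)
    # the confirming run can start a few frames into the transport phase
    # when localization noise breaks a step criterion: refine the event to
    # the knee of the distance-to-AP series around the run start
    idx = _refine_knee(times_s, d, idx, thr)
    pre, post = phase_speeds(times_s, xyz, idx, p, thr)
    return CaptureEvent(
        chromosome=chromosome,
        time_min=float(times_s[idx] / 60.0),
        frame_index=idx,
        rule=rule,
        pre_speed=pre,
        post_speed=post,
    )


def phase_speeds(
    times_s,
    positions,
    event_frame: int,
    p,
    thresholds: DetectionThresholds | None = None,
) -> tuple[float | None, float | None]:
    """Mean speeds (µm/min) before and after an event frame.

    Speeds are displacement over a ``speed_window``-frame span divided by
    the elapsed time. Frames in the arrival plateau (smoothed speed below
    ``arrival_speed`` within ``arrival_distance`` of the AP) are excluded
    from the post-event estimate. A side without one full window is
    reported as None.
    """
    thr = thresholds or DetectionThresholds()
    times_s = np.asarray(times_s, dtype=float)
    xyz = np.atleast_2d(np.asarray(positions, dtype=float))
    p = np.asarray(p, dtype=float)
    n = xyz.shape[0]
    if not 0 <= event_frame < n:
        raise ValidationError(f"event_frame {event_frame} outside trajectory of {n} frames")
    w = thr.speed_window

    # arrival plateau: sustained slow motion close to the AP; speed over a
    # w-frame span, which is robust to frame-to-frame localization noise
    win_speed = np.full(n, np.inf)
    if n > w:
        i = np.arange(n - w)
        win_speed[i + w] = (
            np.linalg.norm(xyz[i + w] - xyz[i], axis=1) / (times_s[i + w] - times_s[i]) * 60.0
        )
    d = np.linalg.norm(xyz - p, axis=1)
    plateau = (win_speed < thr.arrival_speed) & (d < thr.arrival_distance)
    stop = n
    after = np.nonzero(plateau[event_frame:])[0]
    if after.size:
        stop = event_frame + int(after[0])

    def window_speed(lo: int, hi: int) -> float | None:
        # median over windows [i, i+w] fully inside [lo, hi); the median is
        # robust to residual contamination at the phase edges
        if hi - lo <= w:
            return None
        i = np.arange(lo, hi - w)
        span = times_s[i + w] - times_s[i]
        dist = np.linalg.norm(xyz[i + w] - xyz[i], axis=1)
        return float(np.median(dist / span) * 60.0)

    pre = window_speed(0, event_frame + 1)
    post = window_speed(event_frame, stop)
    return pre, post


@dataclass(frozen=True)
class CaptureStatistics:
    """Summary of a set of capture times (minutes after NEBD)."""

    n: int
    mean_min: float | None
    sd_min: float | None
    bin_edges_min: np.ndarray
    counts: np.ndarray
    modal_bin_min: tuple[float, float] | None   # (left, right) edge of the fullest bin


def capture_statistics(
    capture_times_min,
    bin_width: float = 0.5,
    t_max: float = 20.0,
) -> CaptureStatistics:
    """Mean, SD and a 0.5-min-binned histogram of capture times."""
    times = np.asarray(list(capture_times_min), dtype=float)
    times = times[~np.isnan(times)]
    edges = np.arange(0.0, t_max + bin_width / 2, bin_width)
    if times.size == 0:
        return CaptureStatistics(0, None, None, edges, np.zeros(len(edges) - 1, dtype=int), None)
    counts, _ = np.histogram(times, bins=edges)
    k = int(np.argmax(counts))
    return CaptureStatistics(
        n=int(times.size),
        mean_min=float(np.mean(times)),
        sd_min=float(np.std(times, ddof=1)) if times.size > 1 else None,
        bin_edges_min=edges,
        counts=counts,
        modal_bin_min=(float(edges[k]), float(edges[k + 1])),
    )


def analyze_trajectories(
    traj: pd.DataFrame,
    p,
    thresholds: DetectionThresholds | None = None,
) -> pd.DataFrame:
    """Run capture-event detection on every track of a trajectory table.

    ``traj`` uses the canonical long format (oocyte, chromosome, t_s,
    x_um, y_um, z_um). Returns one row per track with the detected event
    (NaN fields where no event was found).
    """
    rows = []
    for (oocyte, chrom), g in traj.groupby(["oocyte", "chromosome"], sort=True):
        g = g.sort_values("t_s")
        xyz = g[["x_um", "y_um", "z_um"]].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = detect_capture_event(
                g["t_s"].to_numpy(), xyz, p, thresholds, chromosome=int(chrom)
            )
        rows.append(
            {
                "oocyte": oocyte,
                "chromosome": chrom,
                "detected": ev is not None,
                "capture_time_min": ev.time_min if ev else np.nan,
                "rule": ev.rule if ev else "",
                "pre_speed_um_min": (ev.pre_speed if ev and ev.pre_speed is not None else np.nan),
                "post_speed_um_min": (ev.post_speed if ev and ev.post_speed is not None else np.nan),
            }
        )
    return pd.DataFrame(rows)
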