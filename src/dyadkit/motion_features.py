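"""Hand-movement descriptors: space, dynamics, pauses and curvature.

From a normalized 2D trajectory with missing frames the module computes
a 21-element descriptor vector covering

* the space explored by the hand (coordinate ranges and SDs, the exact
  farthest-pair distance, path length),
* its dynamics (speed and acceleration summaries from finite
  differences inside maximal runs of consecutive visible frames),
* movement pauses — intervals of at least 4 s during which the speed
  stays below a threshold, by default 2% of the trajectory's own
  maximum smoothed speed so the definition is invariant to camera zoom,
* and the curvature of the planar curve,
  kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2),
  undefined where the hand is (nearly) motionless.

Derivatives are never taken across invisibility gaps; descriptors that
cannot be computed (too few visible frames, no motherese labels, ...)
are reported as NaN and propagate to the classifier's imputation step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .config import RunConfig
from .tracking import Trajectory

logger = logging.getLogger(__name__)

#: The 21 hand-movement feature names, in canonical order.
MOTION_FEATURES = [
    "xRange", "yRange", "xSd", "ySd", "maxPairDist", "pathLength",
    "visibleFraction", "velMean", "velSd", "velMax", "accMean", "accSd",
    "accMax", "curvMean", "curvSd", "curvMax", "pauseCount",
    "pauseTotalDur_s", "pauseRelTime", "pauseMeanDur_s",
    "movementUnitCount",
]


@dataclass(frozen=True)
class PauseInterval:
    """A motionless episode of at least the minimum pause duration."""

    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def visible_runs(traj: Trajectory, min_len: int = 1) -> list[slice]:
    """Maximal runs of consecutive visible frames, as index slices.

    Consecutive means adjacent positions in the array AND adjacent
    frame indices — a dropped frame breaks a run even if the file omits
    the row.
    """
    runs = []
    start = None
    prev_frame = None
    for i in range(len(traj)):
        contiguous = prev_frame is not None and traj.frames[i] == prev_frame + 1
        if traj.visible[i]:
            if start is None:
                start = i
            elif not contiguous:
                runs.append(slice(start, i))
                start = i
        elif start is not None:
            runs.append(slice(start, i))
            start = None
        prev_frame = traj.frames[i]
    if start is not None:
        runs.append(slice(start, len(traj)))
    return [r for r in runs if r.stop - r.start >= min_len]


def select_window(traj: Trajectory, window_s: float = 60.0) -> Trajectory:
    """Contiguous window maximizing the visible-frame fraction.

    Emulates the clip-selection rule: one minute is kept out of a longer
    recording, chosen so the hand is visible as much as possible.  Ties
    break toward the earliest start.  A trajectory shorter than the
    window is returned whole with a warning.
    """
    n_win = int(round(window_s * traj.fps))
    n = len(traj)
    if n <= n_win:
        if n < n_win:
            logger.warning("trajectory shorter than %.0f s window", window_s)
        return traj
    counts = np.convolve(traj.visible.astype(int),
                         np.ones(n_win, dtype=int), mode="valid")
    start = int(np.argmax(counts))  # argmax returns the first maximum
    sl = slice(start, start + n_win)
    return Trajectory(fps=traj.fps, frames=traj.frames[sl] - traj.frames[start],
                      x=traj.x[sl], y=traj.y[sl], visible=traj.visible[sl],
                      normalization_factor=traj.normalization_factor)


def max_pair_distance(points: np.ndarray) -> float:
    """Exact farthest-pair (diameter) of a 2D point set."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    if len(points) <= 2000:
        return float(pdist(points).max())
    # reduce to the convex hull first for large inputs
    from scipy.spatial import ConvexHull, QhullError
    try:
        hull = ConvexHull(points)
        return float(pdist(points[hull.vertices]).max())
    except QhullError:  # degenerate (collinear) input
        return float(pdist(points).max())


def spatial_descriptors(traj: Trajectory) -> dict[str, float]:
    """Space explored by the hand, over visible frames only."""
    pts = traj.xy()[traj.visible]
    if len(pts) < 2:
        return {k: float("nan")
                for k in ("xRange", "yRange", "xSd", "ySd", "maxPairDist")}
    return {
        "xRange": float(np.ptp(pts[:, 0])),
        "yRange": float(np.ptp(pts[:, 1])),
        "xSd": float(np.std(pts[:, 0])),
        "ySd": float(np.std(pts[:, 1])),
        "maxPairDist": max_pair_distance(pts),
    }


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shrinking window at the run edges."""
    if window <= 1 or len(a) < 2:
        return a.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(a.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[:len(a)]


def kinematics(traj: Trajectory, smooth_window: int = 5
               ) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Speed and acceleration series plus their summary statistics.

    Coordinates are smoothed by a centered moving average within each
    maximal visible run, then differentiated with central finite
    differences; nothing is differentiated across a gap.  The returned
    series are per-frame and NaN where undefined.  Summaries pool all
    defined samples.  Path length sums the smoothed step lengths inside
    runs.
    """
    n = len(traj)
    dt = 1.0 / traj.fps
    speed = np.full(n, np.nan)
    accel = np.full(n, np.nan)
    path = 0.0
    any_run = False
    for run in visible_runs(traj, min_len=3):
        any_run = True
        x = _smooth(traj.x[run], smooth_window)
        y = _smooth(traj.y[run], smooth_window)
        path += float(np.sum(np.hypot(np.diff(x), np.diff(y))))
        vx = np.gradient(x, dt)
        vy = np.gradient(y, dt)
        speed[run] = np.hypot(vx, vy)
        m = run.stop - run.start
        if m >= 3:
            ax = np.gradient(vx, dt)
            ay = np.gradient(vy, dt)
            accel[run] = np.hypot(ax, ay)
    v = speed[~np.isnan(speed)]
    a = accel[~np.isnan(accel)]
    if not any_run or len(v) == 0:
        stats = {k: float("nan") for k in ("velMean", "velSd", "velMax",
                                           "accMean", "accSd", "accMax",
                                           "pathLength")}
        return speed, accel, stats
    stats = {
        "velMean": float(v.mean()), "velSd": float(v.std()),
        "velMax": float(v.max()),
        "accMean": float(a.mean()) if len(a) else float("nan"),
        "accSd": float(a.std()) if len(a) else float("nan"),
        "accMax": float(a.max()) if len(a) else float("nan"),
        "pathLength": path,
    }
    return speed, accel, stats


def detect_pauses(speed: np.ndarray, threshold: float, fps: float,
                  min_dur_s: float = 4.0
                  ) -> tuple[list[PauseInterval], dict[str, float]]:
    """Movement pauses: maximal sub-threshold runs of at least min_dur_s.

    The speed series carries NaN at undefined samples (invisible frames
    or run edges); a pause never spans such a gap.  ``pauseRelTime`` is
    the pause time divided by the time over which speed is defined.
    """
    speed = np.asarray(speed, dtype=float)
    below = (speed < threshold) & ~np.isnan(speed)
    min_frames = int(round(min_dur_s * fps))
    pauses: list[PauseInterval] = []
    i = 0
    n = len(speed)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_frames:
                pauses.append(PauseInterval(i / fps, j / fps))
            i = j
        else:
            i += 1
    defined = int(np.sum(~np.isnan(speed)))
    total = sum(p.duration_s for p in pauses)
    stats = {
        "pauseCount": float(len(pauses)),
        "pauseTotalDur_s": total,
        "pauseRelTime": total / (defined / fps) if defined else float("nan"),
        "pauseMeanDur_s": total / len(pauses) if pauses else 0.0,
    }
    return pauses, stats


def curvature(traj: Trajectory, smooth_window: int = 5,
              speed_epsilon: float | None = None
              ) -> tuple[np.ndarray, dict[str, float]]:
    """Curvature series kappa(t) and its summaries.

    kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2) with finite-difference
    derivatives inside visible runs of at least 5 frames.  Samples where
    the speed falls below ``speed_epsilon`` are excluded: curvature of a
    near-stationary point is numerically meaningless.
    """
    n = len(traj)
    dt = 1.0 / traj.fps
    kappa = np.full(n, np.nan)
    speeds = []
    pieces = []
    for run in visible_runs(traj, min_len=5):
        x = _smooth(traj.x[run], smooth_window)
        y = _smooth(traj.y[run], smooth_window)
        x1, y1 = np.gradient(x, dt), np.gradient(y, dt)
        x2, y2 = np.gradient(x1, dt), np.gradient(y1, dt)
        sp = np.hypot(x1, y1)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.abs(x1 * y2 - y1 * x2) / sp ** 3
        # one-sided derivatives at run edges are first-order only;
        # drop two samples at each end where kappa is unreliable
        k[:2] = np.nan
        k[-2:] = np.nan
        pieces.append((run, k, sp))
        speeds.append(sp)
    if not pieces:
        return kappa, {k: float("nan")
                       for k in ("curvMean", "curvSd", "curvMax")}
    if speed_epsilon is None:
        vmax = max(float(sp.max()) for sp in speeds)
        speed_epsilon = 0.02 * vmax
    for run, k, sp in pieces:
        k = np.where(sp >= speed_epsilon, k, np.nan)
        kappa[run] = k
    valid = kappa[~np.isnan(kappa)]
    if len(valid) == 0:
        stats = {k: float("nan") for k in ("curvMean", "curvSd", "curvMax")}
    else:
        stats = {"curvMean": float(valid.mean()),
                 "curvSd": float(valid.std()),
                 "curvMax": float(valid.max())}
    return kappa, stats


def movement_units(speed: np.ndarray, threshold: float) -> int:
    """Number of maximal supra-threshold speed runs (movement bursts)."""
    above = (np.asarray(speed) >= threshold) & ~np.isnan(speed)
    return int(np.sum(above[1:] & ~above[:-1]) + (1 if len(above) and above[0] else 0))


def motion_features(traj: Trajectory,
                    config: RunConfig | None = None) -> dict[str, float]:
    """Assemble the full 21-element hand-movement descriptor vector."""
    config = config or RunConfig()
    feats: dict[str, float] = {}
    feats.update(spatial_descriptors(traj))
    speed, _accel, kin = kinematics(traj, config.smooth_window)
    feats.update(kin)
    feats["visibleFraction"] = traj.visible_fraction

    if config.pause_speed_absolute is not None:
        threshold = config.pause_speed_absolute
    elif np.any(~np.isnan(speed)):
        vmax = float(np.nanmax(speed))
        # a motionless trajectory is one long pause, not zero pauses
        threshold = config.pause_speed_threshold * vmax if vmax > 0 else np.inf
    else:
        threshold = float("nan")
    if np.isnan(threshold):
        feats.update({"pauseCount": float("nan"),
                      "pauseTotalDur_s": float("nan"),
                      "pauseRelTime": float("nan"),
                      "pauseMeanDur_s": float("nan"),
                      "movementUnitCount": float("nan")})
    else:
        _, pstats = detect_pauses(speed, threshold, traj.fps,
                                  config.pause_min_s)
        feats.update(pstats)
        feats["movementUnitCount"] = float(movement_units(speed, threshold))

    _, cstats = curvature(traj, config.smooth_window,
                          None if np.isnan(threshold) else threshold)
    feats.update(cstats)
    feats = {k: feats[k] for k in MOTION_FEATURES}
    return feats
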