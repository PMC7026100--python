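"""Synthetic mother-infant dyads with controllable group effects.

Every downstream stage of the pipeline is testable without clinical
recordings: this module generates

* two-speaker vocalization timelines from a renewal process with a
  controllable probability ``p_sync`` that the infant answers a mother
  vocalization inside the synchrony window,
* 2D hand trajectories from a first-order random walk with planted
  pause episodes, abrupt velocity redraws and occlusion gaps,
* blob videos (a colored disk on a noisy background) for the tracker,
* voiced speech segments with motherese-like (high, strongly modulated
  F0) vs flat prosody for the motherese classifier,
* whole cohorts (TD / WS- / WS+) whose group parameter contrasts follow
  the reported correlation signs: infants in the WS+ group vocalize
  less, answer their mothers less often, move less vigorously and spend
  more time motionless.

The generating parameters are stored with each dyad as ground truth so
recovery tests can compare extracted features against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AnnotationRecord
from .tracking import Trajectory

#: Planted pause episodes dwell at least this long before their
#: exponential tail, so every episode clears the 4 s detection floor
#: and the planted rate is recoverable.
PAUSE_DWELL_MIN_S = 4.5

_MIN_EVENT_MS = 200


@dataclass(frozen=True)
class TimelineParams:
    """Generating parameters of one dyad's vocalization timeline."""

    mother_voc_rate: float = 8.0          # events / minute
    mother_voc_dur_mean_ms: float = 1500.0
    infant_voc_rate: float = 5.0          # background events / minute
    infant_voc_dur_mean_ms: float = 800.0
    p_sync: float = 0.5
    motherese_fraction: float = 0.5
    atypical_fraction: float = 0.05
    other_noise_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mother_voc_rate < 0 or self.infant_voc_rate < 0:
            raise ValueError("rates must be non-negative")
        for name in ("p_sync", "motherese_fraction", "atypical_fraction",
                     "other_noise_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class MotionParams:
    """Generating parameters of one dyad's hand trajectory."""

    step_sd: float = 0.012                # scene units / frame
    pause_rate: float = 1.5               # episodes / minute
    pause_dur_mean_s: float = 6.0
    turn_abruptness: float = 0.08         # velocity redraw prob / frame
    occlusion_rate: float = 1.0           # gaps / minute
    occlusion_dur_mean_s: float = 1.5

    def __post_init__(self) -> None:
        for name in ("step_sd", "pause_rate", "pause_dur_mean_s",
                     "turn_abruptness", "occlusion_rate",
                     "occlusion_dur_mean_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GroupParams:
    timeline: TimelineParams
    motion: MotionParams


#: Study-condition defaults per outcome group.  WS+ infants vocalize
#: less and answer less often than WS- (matching the negative
#: correlations of vocalization count and synchrony ratios with the
#: WS+ class), move with smaller velocity/acceleration variance, and
#: pause more.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "TD": GroupParams(
        TimelineParams(mother_voc_rate=8.0, infant_voc_rate=7.0, p_sync=0.65,
                       motherese_fraction=0.55, atypical_fraction=0.02),
        MotionParams(step_sd=0.014, pause_rate=0.5, pause_dur_mean_s=6.0,
                     occlusion_rate=1.0),
    ),
    "WSminus": GroupParams(
        TimelineParams(mother_voc_rate=8.0, infant_voc_rate=4.0, p_sync=0.40,
                       motherese_fraction=0.50, atypical_fraction=0.06),
        MotionParams(step_sd=0.009, pause_rate=2.5, pause_dur_mean_s=6.5,
                     occlusion_rate=1.0),
    ),
    "WSplus": GroupParams(
        TimelineParams(mother_voc_rate=8.0, infant_voc_rate=1.5, p_sync=0.12,
                       motherese_fraction=0.45, atypical_fraction=0.12),
        MotionParams(step_sd=0.005, pause_rate=3.5, pause_dur_mean_s=8.0,
                     occlusion_rate=1.0),
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: 19 TD + 22 WS- + 10 WS+ mirrors the study design."""

    n_td: int = 19
    n_ws_minus: int = 22
    n_ws_plus: int = 10
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    audio_duration_s: float = 180.0
    motion_duration_s: float = 60.0
    fps: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_td, self.n_ws_minus, self.n_ws_plus) < 0:
            raise ValueError("counts must be non-negative")
        missing = {"TD", "WSminus", "WSplus"} - set(self.group_params)
        if missing:
            raise ValueError(f"missing group params: {sorted(missing)}")


@dataclass
class MotionTruth:
    """Ground truth of a generated trajectory."""

    params: MotionParams
    pause_intervals: list[tuple[int, int]]      # frame ranges, half-open
    occlusion_intervals: list[tuple[int, int]]


@dataclass
class DyadRecord:
    dyad_id: str
    group: str
    timeline: list[AnnotationRecord]
    trajectory: Trajectory
    truth_timeline: TimelineParams
    truth_motion: MotionTruth


# ---------------------------------------------------------------------------
# timelines


def _renewal_events(rate_per_min: float, dur_mean_ms: float,
                    duration_ms: int, rng: np.random.Generator
                    ) -> list[tuple[int, int]]:
    """(onset, offset) events of a renewal process, clipped to duration."""
    if rate_per_min <= 0:
        return []
    events = []
    t = 0.0
    mean_gap_ms = 60000.0 / rate_per_min
    while True:
        t += rng.exponential(mean_gap_ms)
        if t >= duration_ms - _MIN_EVENT_MS:
            break
        dur = max(_MIN_EVENT_MS, rng.exponential(dur_mean_ms))
        events.append((int(t), int(min(t + dur, duration_ms))))
    return events


def _truncate_self_overlap(events: list[tuple[int, int]]
                           ) -> list[tuple[int, int]]:
    events = sorted(set(events))
    out: list[tuple[int, int]] = []
    for s, e in events:
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], s)  # truncate the earlier event
            if out[-1][1] - out[-1][0] <= 0:
                out.pop()
        out.append((s, e))
    return [(s, e) for s, e in out if e > s]


def make_timeline(params: TimelineParams, duration_ms: int, seed: int,
                  synchrony_window_ms: int = 3000) -> list[AnnotationRecord]:
    """Generate one dyad's annotation timeline.

    Mother events follow a renewal process (exponential inter-onset,
    exponential durations).  After each mother vocalization, with
    probability ``p_sync`` an infant response onset is placed uniformly
    inside the synchrony window after the mother turn's offset; further
    infant vocalizations arrive independently at ``infant_voc_rate``.
    Same-speaker overlap is resolved by truncating the earlier event.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    mother = _renewal_events(params.mother_voc_rate,
                             params.mother_voc_dur_mean_ms, duration_ms, rng)
    mother = _truncate_self_overlap(mother)
    mother_records = []
    for s, e in mother:
        if rng.random() < params.other_noise_fraction:
            mother_records.append(AnnotationRecord("mother", "other_noise", s, e))
        else:
            label = bool(rng.random() < params.motherese_fraction)
            mother_records.append(AnnotationRecord(
                "mother", "vocalization", s, e, motherese=label))

    infant_events = _renewal_events(params.infant_voc_rate,
                                    params.infant_voc_dur_mean_ms,
                                    duration_ms, rng)
    for rec in mother_records:
        if rec.category != "vocalization" or rng.random() >= params.p_sync:
            continue
        hi = min(rec.offset_ms + synchrony_window_ms, duration_ms - 1)
        if hi <= rec.offset_ms + 1:
            continue  # no room for a response before the session ends
        onset = int(rng.integers(rec.offset_ms + 1, hi + 1))
        dur = max(_MIN_EVENT_MS, rng.exponential(params.infant_voc_dur_mean_ms))
        infant_events.append((onset, int(min(onset + dur, duration_ms))))
    infant_events = _truncate_self_overlap(infant_events)
    infant_records = []
    for s, e in infant_events:
        category = ("atypical_vocalization"
                    if rng.random() < params.atypical_fraction
                    else "vocalization")
        infant_records.append(AnnotationRecord("infant", category, s, e))

    records = mother_records + infant_records
    records.sort(key=lambda r: (r.onset_ms, r.offset_ms, r.speaker))
    return records


# ---------------------------------------------------------------------------
# trajectories


def _poisson_episodes(rate_per_min: float, dur_mean_s: float, min_dur_s: float,
                      n_frames: int, fps: float, rng: np.random.Generator,
                      margin_s: float = 1.0) -> list[tuple[int, int]]:
    """Non-overlapping (start, stop) frame intervals of planted episodes.

    The Poisson count is preserved by rejection placement (episodes are
    re-drawn rather than dropped or truncated on collision), so the
    realized episode rate is an unbiased match of ``rate_per_min`` as
    long as the session is far from saturated.
    """
    duration_min = n_frames / fps / 60.0
    count = rng.poisson(rate_per_min * duration_min)
    episodes: list[tuple[int, int]] = []
    tail_mean = max(dur_mean_s - min_dur_s, 0.1)
    margin = int(round(margin_s * fps))
    for _ in range(count):
        for _attempt in range(200):
            dur = int(round((min_dur_s + rng.exponential(tail_mean)) * fps))
            if dur >= n_frames:
                continue
            start = int(rng.integers(0, n_frames - dur + 1))
            stop = start + dur
            if all(stop + margin <= s or start >= e + margin
                   for s, e in episodes):
                episodes.append((start, stop))
                break
    return sorted(episodes)


def make_motion(params: MotionParams, duration_s: float = 60.0,
                fps: float = 25.0, seed: int = 0
                ) -> tuple[Trajectory, MotionTruth]:
    """Generate a trajectory together with its ground-truth episodes."""
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    pauses = _poisson_episodes(params.pause_rate, params.pause_dur_mean_s,
                               PAUSE_DWELL_MIN_S, n, fps, rng)
    occlusions = _poisson_episodes(params.occlusion_rate,
                                   params.occlusion_dur_mean_s, 0.2,
                                   n, fps, rng)
    in_pause = np.zeros(n, dtype=bool)
    for s, e in pauses:
        in_pause[s:e] = True
    visible = np.ones(n, dtype=bool)
    for s, e in occlusions:
        visible[s:e] = False

    x = np.empty(n)
    y = np.empty(n)
    pos = rng.uniform(0.25, 0.75, size=2)
    vel = rng.normal(0, params.step_sd, size=2)
    jitter_sd = params.step_sd * 1e-3
    was_paused = False
    for t in range(n):
        if in_pause[t]:
            step = rng.normal(0, jitter_sd, size=2)
            was_paused = True
        else:
            if was_paused or rng.random() < params.turn_abruptness:
                vel = rng.normal(0, params.step_sd, size=2)
                was_paused = False
            step = vel
        pos = pos + step
        # reflect at the unit scene box
        for d in range(2):
            if pos[d] < 0.0:
                pos[d] = -pos[d]
                vel[d] = -vel[d]
            elif pos[d] > 1.0:
                pos[d] = 2.0 - pos[d]
                vel[d] = -vel[d]
        x[t], y[t] = pos
    x[~visible] = np.nan
    y[~visible] = np.nan
    traj = Trajectory(fps=fps, frames=np.arange(n), x=x, y=y, visible=visible)
    return traj, MotionTruth(params, pauses, occlusions)


def make_trajectory(params: MotionParams, duration_s: float = 60.0,
                    fps: float = 25.0, seed: int = 0) -> Trajectory:
    """Trajectory only; see :func:`make_motion` for the ground truth."""
    return make_motion(params, duration_s, fps, seed)[0]


# ---------------------------------------------------------------------------
# videos


def scene_to_pixel(values: np.ndarray, size: int, margin: int) -> np.ndarray:
    """Map scene coordinates in [0, 1] to pixel coordinates."""
    return margin + np.asarray(values) * (size - 1 - 2 * margin)


def make_video(traj: Trajectory, blob_color=(230, 200, 30), noise_sd: float = 8.0,
               seed: int = 0, image_size: tuple[int, int] = (80, 80),
               blob_radius: int = 5,
               background=(90, 110, 90)) -> list[np.ndarray]:
    """Render a trajectory as frames with a colored disk on a noisy field.

    Scene coordinates in [0, 1] are mapped into the image with a margin
    of ``blob_radius + 2`` pixels; occluded frames contain no disk.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    margin = blob_radius + 2
    yy, xx = np.mgrid[0:h, 0:w]
    frames = []
    for i in range(len(traj)):
        frame = np.tile(np.asarray(background, dtype=float), (h, w, 1))
        if traj.visible[i]:
            cx = scene_to_pixel(traj.x[i], w, margin)
            cy = scene_to_pixel(traj.y[i], h, margin)
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= blob_radius ** 2
            frame[mask] = np.asarray(blob_color, dtype=float)
        frame += rng.normal(0, noise_sd, frame.shape)
        frames.append(np.clip(frame, 0, 255).astype(np.uint8))
    return frames


# ---------------------------------------------------------------------------
# speech segments


def make_speech_segment(kind: str, duration_s: float, sample_rate: float = 16000,
                        seed: int = 0) -> np.ndarray:
    """Voiced segment with motherese-like or flat prosody.

    ``kind="motherese"``: high mean F0 (~280 Hz) with wide slow
    modulation and a rising-falling glide, brighter harmonic spectrum —
    the exaggerated prosody of infant-directed speech.
    ``kind="other"``: lower (~190 Hz), nearly flat F0 with mild jitter
    and a darker spectrum.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    if kind == "motherese":
        base = rng.uniform(250.0, 320.0)
        depth = rng.uniform(60.0, 110.0)
        mod_hz = rng.uniform(1.0, 2.5)
        f0 = (base + depth * np.sin(2 * np.pi * mod_hz * t + rng.uniform(0, 6))
              + 40.0 * np.sin(np.pi * t / duration_s))
        harmonic_amps = (1.0, 0.7, 0.5)
    elif kind == "other":
        base = rng.uniform(170.0, 210.0)
        f0 = base + rng.uniform(3.0, 10.0) * np.sin(
            2 * np.pi * rng.uniform(0.3, 0.8) * t)
        harmonic_amps = (1.0, 0.35, 0.1)
    else:
        raise ValueError(f"unknown segment kind {kind!r}")
    phase = 2 * np.pi * np.cumsum(f0) / sample_rate
    wave = sum(a * np.sin((k + 1) * phase) for k, a in enumerate(harmonic_amps))
    envelope = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(2, 4) * t) ** 2
    wave = wave * envelope + rng.normal(0, 0.01, n)
    return (0.3 * wave / np.max(np.abs(wave))).astype(float)


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(spec: CohortSpec) -> list[DyadRecord]:
    """Generate the full cohort, reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records = []
    duration_ms = int(round(spec.audio_duration_s * 1000))
    for group, count in (("TD", spec.n_td), ("WSminus", spec.n_ws_minus),
                         ("WSplus", spec.n_ws_plus)):
        gp = spec.group_params[group]
        for i in range(count):
            s1, s2 = rng.integers(0, 2 ** 31, size=2)
            timeline = make_timeline(gp.timeline, duration_ms, int(s1))
            traj, truth = make_motion(gp.motion, spec.motion_duration_s,
                                      spec.fps, int(s2))
            records.append(DyadRecord(
                dyad_id=f"{group}_{i:03d}", group=group, timeline=timeline,
                trajectory=traj, truth_timeline=gp.timeline,
                truth_motion=truth))
    return records
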