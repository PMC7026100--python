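"""Bootstrap particle filter for wristband tracking with occlusion handling.

The tracker follows the classic predict / observe (weigh) / estimate cycle
of a bootstrap particle filter.  Hand motion during infant play is highly
nonlinear — abrupt changes in direction and speed — so the dynamic model
is first order (position + velocity with Gaussian diffusion on both),
which recovers quickly after a velocity change instead of committing to a
smooth trajectory.  Occlusion is handled by augmenting each particle's
state with a boolean visibility flag: particles flagged invisible ignore
the image and receive a fixed occlusion likelihood, so when the target
color disappears the invisible sub-population takes over the posterior
and the frame is reported as missing rather than hallucinated.

The observation model is a Bhattacharyya similarity between the RGB
histogram of a small patch at the particle position and a reference
histogram of the target color — the standard likelihood for color-blob
particle filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

_HIST_BINS = 8  # per RGB channel; bin width 32 on uint8 values


@dataclass
class Trajectory:
    """Timestamped 2D positions with per-frame visibility.

    ``x``/``y`` are NaN wherever ``visible`` is False (missing
    coordinates).  A 60 s recording at 25 fps holds 1500 coordinate
    pairs.
    """

    fps: float
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    visible: np.ndarray
    normalization_factor: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.visible) == n):
            raise ValueError("frame/coordinate arrays must share one length")
        if n > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    @property
    def visible_fraction(self) -> float:
        return float(self.visible.mean()) if len(self) else 0.0

    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array, NaN on missing frames."""
        return np.column_stack([self.x, self.y])


@dataclass
class TrackerConfig:
    """Particle filter knobs; all values are artifact defaults.

    ``target_color`` is the RGB color of the tracked blob (uint8 scale).
    ``likelihood_floor`` is the minimum Bhattacharyya similarity of the
    best particle for the target to count as seen in a frame.
    """

    n_particles: int = 500
    process_noise_pos: float = 1.5   # px / frame
    process_noise_vel: float = 0.6   # px / frame^2
    target_color: tuple[int, int, int] = (230, 200, 30)
    patch_radius: int = 4
    likelihood_floor: float = 0.35
    occlusion_likelihood: float = 0.05
    visibility_flip_prob: float = 0.05
    resample_ess_fraction: float = 0.5
    visible_weight_min: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0.0 < self.likelihood_floor < 1.0:
            raise ValueError("likelihood_floor must lie in (0, 1)")


@dataclass
class ParticleSet:
    """State of the filter: positions, velocities, visibility, weights."""

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    visible: np.ndarray
    weights: np.ndarray
    best_likelihood: float = 0.0

    def __len__(self) -> int:
        return len(self.x)

    def normalized(self) -> "ParticleSet":
        total = self.weights.sum()
        if total <= 0:
            w = np.full(len(self), 1.0 / len(self))
        else:
            w = self.weights / total
        return replace(self, weights=w)


def _color_histogram(pixels: np.ndarray) -> np.ndarray:
    """Normalized per-channel histogram, flattened to 3*_HIST_BINS."""
    pixels = np.asarray(pixels, dtype=np.uint8).reshape(-1, 3)
    bins = np.minimum(pixels // (256 // _HIST_BINS), _HIST_BINS - 1)
    hist = np.zeros((3, _HIST_BINS))
    for c in range(3):
        hist[c] = np.bincount(bins[:, c], minlength=_HIST_BINS)
    hist /= hist.sum(axis=1, keepdims=True)
    return hist.ravel()


def reference_histogram(target_color: tuple[int, int, int]) -> np.ndarray:
    """Histogram of an idealized patch uniformly filled with the target color."""
    patch = np.tile(np.asarray(target_color, dtype=np.uint8), (4, 1))
    return _color_histogram(patch)


def bhattacharyya(h1: np.ndarray, h2: np.ndarray) -> float:
    """Bhattacharyya coefficient between two normalized histograms.

    Equals 1 for identical histograms, 0 for disjoint support.  With
    per-channel histograms stacked, the mean over channels is returned
    so the value stays in [0, 1].
    """
    h1 = np.asarray(h1).reshape(3, _HIST_BINS)
    h2 = np.asarray(h2).reshape(3, _HIST_BINS)
    return float(np.mean(np.sqrt(h1 * h2).sum(axis=1)))


def _patch_similarities(particles: ParticleSet, frame: np.ndarray,
                        config: TrackerConfig) -> np.ndarray:
    """Bhattacharyya similarity of the patch at each particle to the target."""
    h, w = frame.shape[:2]
    r = config.patch_radius
    ref = reference_histogram(config.target_color).reshape(3, _HIST_BINS)

    cx = np.clip(np.round(particles.x).astype(int), r, w - 1 - r)
    cy = np.clip(np.round(particles.y).astype(int), r, h - 1 - r)
    offs = np.arange(-r, r + 1)
    # (n, patch, patch, 3) gather, then per-channel histograms per particle
    rows = cy[:, None, None] + offs[None, :, None]
    cols = cx[:, None, None] + offs[None, None, :]
    patches = frame[rows, cols]  # (n, 2r+1, 2r+1, 3)
    n = len(particles)
    pix = patches.reshape(n, -1, 3)
    bins = np.minimum(pix.astype(np.int32) // (256 // _HIST_BINS),
                      _HIST_BINS - 1)
    sims = np.empty(n)
    flat_bins = bins + (np.arange(3) * _HIST_BINS)[None, None, :]
    npix = pix.shape[1]
    for i in range(n):
        hist = np.bincount(flat_bins[i].ravel(), minlength=3 * _HIST_BINS)
        hist = hist.reshape(3, _HIST_BINS) / npix
        sims[i] = np.mean(np.sqrt(hist * ref).sum(axis=1))
    return sims


def predict(particles: ParticleSet, config: TrackerConfig,
            rng: np.random.Generator) -> ParticleSet:
    """Advance each particle one frame under the first-order model.

    Position moves by the particle's velocity plus Gaussian noise;
    velocity diffuses with its own Gaussian noise; the visibility flag
    flips with a small probability so the filter can hypothesize both
    the appearance and disappearance of the target.
    """
    n = len(particles)
    x = particles.x + particles.vx + rng.normal(0, config.process_noise_pos, n)
    y = particles.y + particles.vy + rng.normal(0, config.process_noise_pos, n)
    vx = particles.vx + rng.normal(0, config.process_noise_vel, n)
    vy = particles.vy + rng.normal(0, config.process_noise_vel, n)
    flip = rng.random(n) < config.visibility_flip_prob
    visible = np.where(flip, ~particles.visible, particles.visible)
    return replace(particles, x=x, y=y, vx=vx, vy=vy, visible=visible)


def weigh(particles: ParticleSet, frame_image: np.ndarray,
          config: TrackerConfig) -> ParticleSet:
    """Observation step: color-similarity weights, renormalized.

    Visible-flagged particles are weighted by the Bhattacharyya
    similarity of their local patch to the target color model;
    invisible-flagged particles receive the fixed occlusion likelihood.
    The maximum color similarity among visible particles is stored as
    ``best_likelihood`` for the frame-level visibility decision.
    """
    sims = _patch_similarities(particles, frame_image, config)
    raw = np.where(particles.visible, sims, config.occlusion_likelihood)
    best = float(sims[particles.visible].max()) if particles.visible.any() else 0.0
    if raw.sum() <= 0:
        logger.warning("all-zero observation weights; falling back to uniform")
        raw = np.full(len(particles), 1.0)
    out = replace(particles, weights=raw, best_likelihood=best)
    return out.normalized()


def effective_sample_size(weights: np.ndarray) -> float:
    return 1.0 / float(np.sum(weights ** 2))


def resample(particles: ParticleSet, config: TrackerConfig,
             rng: np.random.Generator) -> ParticleSet:
    """Systematic resampling, applied only when the ESS degenerates.

    Triggered when the effective sample size falls below
    ``resample_ess_fraction * n_particles``; output weights are uniform.
    """
    n = len(particles)
    if effective_sample_size(particles.weights) >= config.resample_ess_fraction * n:
        return particles
    positions = (rng.random() + np.arange(n)) / n
    idx = np.searchsorted(np.cumsum(particles.weights), positions)
    idx = np.clip(idx, 0, n - 1)
    return ParticleSet(
        x=particles.x[idx].copy(), y=particles.y[idx].copy(),
        vx=particles.vx[idx].copy(), vy=particles.vy[idx].copy(),
        visible=particles.visible[idx].copy(),
        weights=np.full(n, 1.0 / n),
        best_likelihood=particles.best_likelihood,
    )


def _detect(frame: np.ndarray, config: TrackerConfig) -> tuple[float, float, float]:
    """Coarse grid scan for the best color match (detection step).

    Returns (x, y, similarity) of the best-matching grid location.
    """
    h, w = frame.shape[:2]
    r = config.patch_radius
    step = max(2, r)
    ys = np.arange(r, h - r, step)
    xs = np.arange(r, w - r, step)
    gx, gy = np.meshgrid(xs, ys)
    probe = ParticleSet(
        x=gx.ravel().astype(float), y=gy.ravel().astype(float),
        vx=np.zeros(gx.size), vy=np.zeros(gx.size),
        visible=np.ones(gx.size, dtype=bool),
        weights=np.full(gx.size, 1.0 / gx.size),
    )
    sims = _patch_similarities(probe, frame, config)
    i = int(np.argmax(sims))
    return float(probe.x[i]), float(probe.y[i]), float(sims[i])


def init_particles(frame: np.ndarray, config: TrackerConfig,
                   rng: np.random.Generator) -> ParticleSet:
    """Initialize the particle cloud around the detected target.

    If no location passes the likelihood floor the cloud is spread
    uniformly over the frame with every particle flagged invisible.
    """
    n = config.n_particles
    h, w = frame.shape[:2]
    bx, by, sim = _detect(frame, config)
    if sim >= config.likelihood_floor:
        x = bx + rng.normal(0, 2.0, n)
        y = by + rng.normal(0, 2.0, n)
        visible = np.ones(n, dtype=bool)
    else:
        x = rng.uniform(0, w - 1, n)
        y = rng.uniform(0, h - 1, n)
        visible = np.zeros(n, dtype=bool)
    return ParticleSet(
        x=x, y=y,
        vx=rng.normal(0, config.process_noise_vel, n),
        vy=rng.normal(0, config.process_noise_vel, n),
        visible=visible,
        weights=np.full(n, 1.0 / n),
    )


def track(frames, config: TrackerConfig | None = None,
          fps: float = 25.0) -> Trajectory:
    """Extract the 2D blob trajectory from a sequence of image frames.

    Per frame, the estimate is the weight-averaged position of the
    visible-flagged particles.  A frame is marked missing when the
    visible-flagged posterior mass or the best color likelihood drops
    below the configured floors.  Deterministic given the config seed.
    """
    config = config or TrackerConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    rng = np.random.default_rng(config.seed)

    particles = init_particles(np.asarray(frames[0]), config, rng)
    xs, ys, vis = [], [], []
    n_missing = 0
    for t, frame in enumerate(frames):
        frame = np.asarray(frame)
        if t > 0:
            particles = predict(particles, config, rng)
            h, w = frame.shape[:2]
            particles.x.clip(0, w - 1, out=particles.x)
            particles.y.clip(0, h - 1, out=particles.y)
        particles = weigh(particles, frame, config)
        vis_mass = float(particles.weights[particles.visible].sum())
        seen = (particles.best_likelihood >= config.likelihood_floor
                and vis_mass >= config.visible_weight_min)
        if seen:
            wv = particles.weights * particles.visible
            wv = wv / wv.sum()
            xs.append(float(np.sum(wv * particles.x)))
            ys.append(float(np.sum(wv * particles.y)))
            vis.append(True)
        else:
            xs.append(np.nan)
            ys.append(np.nan)
            vis.append(False)
            n_missing += 1
            # reacquire by detection if the target reappears elsewhere
            bx, by, sim = _detect(frame, config)
            if sim >= config.likelihood_floor:
                n = len(particles)
                half = n // 2
                particles.x[:half] = bx + rng.normal(0, 2.0, half)
                particles.y[:half] = by + rng.normal(0, 2.0, half)
                particles.visible[:half] = True
        particles = resample(particles, config, rng)
    logger.info("tracked %d frames, %d missing", len(frames), n_missing)
    return Trajectory(fps=fps, frames=np.arange(len(frames)),
                      x=np.array(xs), y=np.array(ys),
                      visible=np.array(vis))


def normalize_trajectory(traj: Trajectory, reference_measured: float,
                         reference_canonical: float) -> Trajectory:
    """Rescale coordinates by a fixed reference length ratio.

    Camera zoom differs between recordings; dividing the canonical
    length of a reference object by its measured length in the frame
    gives a per-recording scale factor that makes trajectories
    metrically comparable.
    """
    if reference_measured <= 0 or reference_canonical <= 0:
        raise ValueError("reference lengths must be positive")
    factor = reference_canonical / reference_measured
    return Trajectory(
        fps=traj.fps, frames=traj.frames.copy(),
        x=traj.x * factor, y=traj.y * factor,
        visible=traj.visible.copy(),
        normalization_factor=traj.normalization_factor * factor,
    )
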