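"""Run configuration for the dyadic interaction pipeline.

All printed constants of the analysis live here: the 150 ms silence
threshold that delimits speech turns, the 3 s synchrony response window,
the 4 s minimum hand-movement pause, the GMM sizes and fusion weight of
the motherese detector, and the PCA variance budget of the outcome
classifier.  Durations for annotations are integer milliseconds;
trajectories are indexed in frames and converted to seconds only through
``fps``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Tunable parameters of the whole pipeline, with study defaults.

    Parameters
    ----------
    fps : float
        Video frame rate (frames/second).
    turn_gap_ms : int
        Silence shorter than this (strictly) is absorbed into a speech
        turn.
    silence_min_ms : int
        A joint silence must be strictly longer than this to count.
    synchrony_window_ms : int
        An infant vocalization onset within this window after a mother
        vocalization offset counts as a response.
    pause_min_s : float
        Minimum duration of a hand-movement pause.
    pause_speed_threshold : float
        Pause speed threshold as a fraction of the trajectory's own
        maximum smoothed speed (scale-free across zoom levels).
    pause_speed_absolute : float or None
        If set, an absolute speed threshold used instead of the relative
        one (scene units / s).
    smooth_window : int
        Centered moving-average window (frames) applied before
        differencing; 5 frames = 200 ms at 25 fps; 1 disables smoothing.
    fusion_lambda : float
        Weight of the segmental stream in motherese score fusion.
    gmm_components_segmental : int
    gmm_components_suprasegmental : int
    pca_variance_kept : float
        Smallest number of principal components whose cumulative
        explained variance reaches this fraction is retained.
    pca_outside_loo : bool
        If True, mimic the laxer protocol of fitting PCA once on the
        full table instead of inside each leave-one-out fold.
    drop_incomplete : bool
        If True, drop dyads with missing features instead of imputing
        training-fold means.
    count_atypical_as_response : bool
        Whether atypical infant vocalizations count as synchrony
        responses (they always count as vocal occupancy).
    random_seed : int
    """

    fps: float = 25.0
    turn_gap_ms: int = 150
    silence_min_ms: int = 150
    synchrony_window_ms: int = 3000
    pause_min_s: float = 4.0
    pause_speed_threshold: float = 0.02
    pause_speed_absolute: float | None = None
    smooth_window: int = 5
    fusion_lambda: float = 0.4
    gmm_components_segmental: int = 12
    gmm_components_suprasegmental: int = 15
    pca_variance_kept: float = 0.95
    pca_outside_loo: bool = False
    drop_incomplete: bool = False
    count_atypical_as_response: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fps", "turn_gap_ms", "silence_min_ms",
                     "synchrony_window_ms", "pause_min_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fusion_lambda <= 1.0:
            raise ValueError("fusion_lambda must lie in [0, 1]")
        if not 0.0 < self.pca_variance_kept <= 1.0:
            raise ValueError("pca_variance_kept must lie in (0, 1]")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


DEFAULT_CONFIG = RunConfig()
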