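"""Motherese (infant-directed speech) detection by two-stream GMM fusion.

Mother vocalizations are scored by two parallel Gaussian-mixture
classifiers and their log-likelihood-ratio scores fused:

* a *segmental* stream over Mel-frequency cepstral coefficient frames
  (13 coefficients, 25 ms windows / 10 ms hop), one diagonal-covariance
  GMM with M = 12 components per class, scored as the mean per-frame
  log-likelihood ratio so segment duration does not dominate;
* a *suprasegmental* (prosodic) stream over one fixed-length vector per
  segment — fundamental-frequency statistics (autocorrelation F0),
  energy statistics, voiced fraction and duration — one GMM with
  M = 15 components per class.

The fused score is ``lambda * segmental + (1 - lambda) * suprasegmental``
with ``lambda = 0.4`` weighting the segmental stream; a segment is
labeled motherese when the fused score is positive (equal priors).

The module also provides the intraclass correlation ICC(2,1) — two-way
random effects, absolute agreement, single rater — used to validate a
classifier against a human rater.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps
from scipy.fft import dct, rfft
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .config import RunConfig
from .speech import SpeechTimeline, Turn

logger = logging.getLogger(__name__)

N_CEPS = 13
FRAME_MS = 25.0
HOP_MS = 10.0
N_MEL_FILTERS = 26

#: Suprasegmental (prosodic) feature vector layout.
SUPRASEGMENTAL_FIELDS = [
    "f0_mean", "f0_sd", "f0_range", "f0_slope",
    "energy_mean", "energy_sd", "energy_range",
    "voiced_fraction", "duration_s",
]


# ---------------------------------------------------------------------------
# feature extraction


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, sample_rate: float) -> np.ndarray:
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2),
                          n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        left, center, right = bins[i], bins[i + 1], bins[i + 2]
        for j in range(left, center):
            if center > left:
                fb[i, j] = (j - left) / (center - left)
        for j in range(center, right):
            if right > center:
                fb[i, j] = (right - j) / (right - center)
    return fb


def _frame_signal(waveform: np.ndarray, sample_rate: float,
                  frame_ms: float, hop_ms: float) -> np.ndarray:
    frame_len = int(round(sample_rate * frame_ms / 1000.0))
    hop = int(round(sample_rate * hop_ms / 1000.0))
    n = len(waveform)
    if n < frame_len:
        return np.empty((0, frame_len))
    n_frames = 1 + (n - frame_len) // hop
    idx = (np.arange(frame_len)[None, :]
           + hop * np.arange(n_frames)[:, None])
    return waveform[idx]


def extract_segmental(waveform: np.ndarray, sample_rate: float) -> np.ndarray:
    """MFCC matrix (frames x 13) of a mono segment.

    25 ms Hamming windows with 10 ms hop; 26 triangular mel filters;
    orthonormal DCT-II; coefficient 0 carries log energy, so amplitude
    scaling shifts it and leaves higher coefficients unchanged.
    """
    waveform = np.asarray(waveform, dtype=float)
    if len(waveform) < 0.1 * sample_rate:
        raise ValueError("segment shorter than 100 ms")
    frames = _frame_signal(waveform, sample_rate, FRAME_MS, HOP_MS)
    frames = frames * np.hamming(frames.shape[1])
    n_fft = int(2 ** np.ceil(np.log2(frames.shape[1])))
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2 / n_fft
    fb = _mel_filterbank(N_MEL_FILTERS, n_fft, sample_rate)
    mel = power @ fb.T
    log_mel = np.log(np.maximum(mel, 1e-12))
    ceps = dct(log_mel, type=2, axis=1, norm="ortho")[:, :N_CEPS]
    return ceps


def _autocorr_f0(frame: np.ndarray, sample_rate: float,
                 f0_min: float = 60.0, f0_max: float = 500.0
                 ) -> tuple[float, float]:
    """(f0_hz, periodicity) of one frame by normalized autocorrelation."""
    frame = frame - frame.mean()
    denom = float(np.dot(frame, frame))
    if denom <= 0:
        return np.nan, 0.0
    ac = np.correlate(frame, frame, mode="full")[len(frame) - 1:]
    ac = ac / denom
    lag_min = int(sample_rate / f0_max)
    lag_max = min(int(sample_rate / f0_min), len(ac) - 2)
    if lag_max <= lag_min + 1:
        return np.nan, 0.0
    window = ac[lag_min:lag_max]
    k = int(np.argmax(window)) + lag_min
    # parabolic interpolation around the peak for sub-sample lag accuracy
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom2 = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom2 if abs(denom2) > 1e-12 else 0.0
    lag = k + float(np.clip(delta, -1, 1))
    return sample_rate / lag, float(y1)


def extract_suprasegmental(waveform: np.ndarray, sample_rate: float,
                           voicing_threshold: float = 0.5) -> dict[str, float]:
    """Prosodic statistics of a mono segment.

    F0 is estimated per 40 ms frame by autocorrelation with parabolic
    peak interpolation; a frame is voiced when its periodicity exceeds
    the threshold and it carries non-negligible energy.  F0 statistics
    (mean, SD, range, and the slope of a linear fit of F0 on time in
    Hz/s) are NaN when no frame is voiced.
    """
    waveform = np.asarray(waveform, dtype=float)
    duration_s = len(waveform) / sample_rate
    frames = _frame_signal(waveform, sample_rate, 40.0, HOP_MS)
    out = {k: float("nan") for k in SUPRASEGMENTAL_FIELDS}
    out["duration_s"] = duration_s
    if len(frames) == 0:
        out["voiced_fraction"] = 0.0
        return out
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    energy_gate = 0.05 * (rms.max() if rms.max() > 0 else 1.0)
    f0s, voiced = [], np.zeros(len(frames), dtype=bool)
    times = HOP_MS / 1000.0 * np.arange(len(frames))
    for i, frame in enumerate(frames):
        if rms[i] < energy_gate:
            continue
        f0, periodicity = _autocorr_f0(frame, sample_rate)
        if np.isfinite(f0) and periodicity > voicing_threshold:
            voiced[i] = True
            f0s.append((times[i], f0))
    out["energy_mean"] = float(rms.mean())
    out["energy_sd"] = float(rms.std())
    out["energy_range"] = float(np.ptp(rms))
    out["voiced_fraction"] = float(voiced.mean())
    if f0s:
        t, f = np.array(f0s).T
        out["f0_mean"] = float(f.mean())
        out["f0_sd"] = float(f.std())
        out["f0_range"] = float(np.ptp(f))
        out["f0_slope"] = float(np.polyfit(t, f, 1)[0]) if len(f) > 1 else 0.0
    return out


def suprasegmental_vector(feats: dict[str, float]) -> np.ndarray:
    return np.array([feats[k] for k in SUPRASEGMENTAL_FIELDS], dtype=float)


# ---------------------------------------------------------------------------
# diagonal-covariance Gaussian mixture


@dataclass
class GaussianMixture:
    """Diagonal-covariance GMM with the EM statistics of its fit."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood_path: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def _component_log_pdf(self, X: np.ndarray) -> np.ndarray:
        """(n, M) log N(x | mu_m, diag(var_m))."""
        X = np.atleast_2d(X)
        d = X.shape[1]
        diff = X[:, None, :] - self.means[None, :, :]
        log_det = np.sum(np.log(self.variances), axis=1)
        maha = np.sum(diff ** 2 / self.variances[None, :, :], axis=2)
        return -0.5 * (d * np.log(2 * np.pi) + log_det[None, :] + maha)

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Per-sample log p(x)."""
        lp = self._component_log_pdf(X) + np.log(self.weights)[None, :]
        return logsumexp(lp, axis=1)

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianMixture":
        return cls(weights=np.array(d["weights"]),
                   means=np.array(d["means"]),
                   variances=np.array(d["variances"]))


VARIANCE_FLOOR = 1e-6


def fit_gmm(X: np.ndarray, n_components: int, seed: int = 0,
            max_iter: int = 200, tol: float = 1e-6) -> GaussianMixture:
    """Fit a diagonal-covariance GMM by EM with k-means initialization.

    The per-iteration total log-likelihood is non-decreasing (recorded
    in ``log_likelihood_path``); iteration stops when its relative
    change drops below ``tol``.  Variances are floored at 1e-6 to keep
    small training sets numerically safe.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < n_components:
        raise ValueError(f"need at least {n_components} vectors, got {n}")
    km = KMeans(n_clusters=n_components, n_init=1, random_state=seed).fit(X)
    means = km.cluster_centers_.copy()
    variances = np.empty((n_components, d))
    weights = np.empty(n_components)
    global_var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    for m in range(n_components):
        mask = km.labels_ == m
        weights[m] = max(mask.sum(), 1) / n
        variances[m] = np.maximum(X[mask].var(axis=0), VARIANCE_FLOOR) \
            if mask.sum() > 1 else global_var
    weights /= weights.sum()
    gmm = GaussianMixture(weights, means, variances)

    prev_ll = -np.inf
    for _ in range(max_iter):
        log_resp = gmm._component_log_pdf(X) + np.log(gmm.weights)[None, :]
        log_norm = logsumexp(log_resp, axis=1)
        ll = float(log_norm.sum())
        gmm.log_likelihood_path.append(ll)
        if ll - prev_ll < tol * abs(ll):
            break
        prev_ll = ll
        resp = np.exp(log_resp - log_norm[:, None])
        nk = resp.sum(axis=0) + 1e-12
        gmm.weights = nk / n
        gmm.means = (resp.T @ X) / nk[:, None]
        diff2 = (X[:, None, :] - gmm.means[None, :, :]) ** 2
        gmm.variances = np.maximum(
            np.einsum("nm,nmd->md", resp, diff2) / nk[:, None],
            VARIANCE_FLOOR)
    return gmm


# ---------------------------------------------------------------------------
# the two-stream classifier


class MothereseClassifier:
    """Two-stream GMM motherese classifier (model object).

    Build with the configuration, call :meth:`fit` with labeled
    waveform segments; the fitted object scores and labels new
    segments.  Serializes to JSON (weights, means, covariances and the
    fusion weight).
    """

    def __init__(self, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.fusion_lambda = self.config.fusion_lambda
        self.models: dict[str, dict[str, GaussianMixture]] = {}
        self.supra_mean: np.ndarray | None = None
        self.supra_sd: np.ndarray | None = None

    @property
    def is_fitted(self) -> bool:
        return bool(self.models)

    def fit(self, waveforms: list[np.ndarray], labels: list[bool],
            sample_rate: float, seed: int | None = None) -> "MothereseClassifier":
        """Train both streams; ``labels`` mark motherese segments."""
        seed = self.config.random_seed if seed is None else seed
        seg_frames = {"motherese": [], "other": []}
        supra_vecs = {"motherese": [], "other": []}
        for wav, is_m in zip(waveforms, labels):
            cls = "motherese" if is_m else "other"
            seg_frames[cls].append(extract_segmental(wav, sample_rate))
            supra_vecs[cls].append(
                suprasegmental_vector(extract_suprasegmental(wav, sample_rate)))
        all_supra = np.array([v for c in ("motherese", "other")
                              for v in supra_vecs[c]])
        all_supra = np.nan_to_num(all_supra)
        self.supra_mean = all_supra.mean(axis=0)
        self.supra_sd = np.where(all_supra.std(axis=0) > 0,
                                 all_supra.std(axis=0), 1.0)
        self.models = {}
        for cls in ("motherese", "other"):
            seg = np.vstack(seg_frames[cls])
            sup = (np.nan_to_num(np.array(supra_vecs[cls])) -
                   self.supra_mean) / self.supra_sd
            m_sup = min(self.config.gmm_components_suprasegmental, len(sup))
            self.models[cls] = {
                "segmental": fit_gmm(
                    seg, self.config.gmm_components_segmental, seed=seed),
                "suprasegmental": fit_gmm(sup, m_sup, seed=seed + 1),
            }
        return self

    def _stream_scores(self, waveform: np.ndarray,
                       sample_rate: float) -> tuple[float, float]:
        seg = extract_segmental(waveform, sample_rate)
        seg_score = float(
            np.mean(self.models["motherese"]["segmental"].log_likelihood(seg))
            - np.mean(self.models["other"]["segmental"].log_likelihood(seg)))
        feats = extract_suprasegmental(waveform, sample_rate)
        vec = suprasegmental_vector(feats)
        if np.any(np.isnan(vec)):
            return seg_score, float("nan")
        vec = (vec - self.supra_mean) / self.supra_sd
        supra_score = float(
            self.models["motherese"]["suprasegmental"].log_likelihood(vec)[0]
            - self.models["other"]["suprasegmental"].log_likelihood(vec)[0])
        return seg_score, supra_score

    def score(self, waveform: np.ndarray, sample_rate: float) -> float:
        """Fused log-likelihood-ratio score; > 0 means motherese."""
        seg_score, supra_score = self._stream_scores(waveform, sample_rate)
        return fused_score(seg_score, supra_score, self.fusion_lambda)

    def predict(self, waveform: np.ndarray, sample_rate: float) -> bool:
        return self.score(waveform, sample_rate) > 0.0

    def label_timeline(self, timeline: SpeechTimeline,
                       waveforms: dict[int, np.ndarray],
                       sample_rate: float) -> SpeechTimeline:
        """Label each mother vocalization turn; others untouched.

        ``waveforms`` maps the index of a turn in ``timeline.turns`` to
        its audio; turns without audio stay unlabeled.
        """
        turns = []
        n_labeled = 0
        for i, t in enumerate(timeline.turns):
            if (t.speaker == "mother" and t.category == "vocalization"
                    and i in waveforms):
                label = self.predict(waveforms[i], sample_rate)
                turns.append(Turn(t.speaker, t.category, t.onset_ms,
                                  t.offset_ms, label))
                n_labeled += 1
            else:
                turns.append(t)
        logger.info("labeled %d mother vocalizations", n_labeled)
        return SpeechTimeline(dyad_id=timeline.dyad_id,
                              duration_ms=timeline.duration_ms, turns=turns)

    def save(self, path: str | Path) -> None:
        data = {
            "fusion_lambda": self.fusion_lambda,
            "supra_mean": self.supra_mean.tolist(),
            "supra_sd": self.supra_sd.tolist(),
            "models": {cls: {stream: gmm.to_dict()
                             for stream, gmm in streams.items()}
                       for cls, streams in self.models.items()},
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def load(cls, path: str | Path,
             config: RunConfig | None = None) -> "MothereseClassifier":
        with open(path) as fh:
            data = json.load(fh)
        obj = cls(config)
        obj.fusion_lambda = data["fusion_lambda"]
        obj.supra_mean = np.array(data["supra_mean"])
        obj.supra_sd = np.array(data["supra_sd"])
        obj.models = {c: {s: GaussianMixture.from_dict(g)
                          for s, g in streams.items()}
                      for c, streams in data["models"].items()}
        return obj


def fused_score(segmental_score: float, suprasegmental_score: float,
                fusion_lambda: float = 0.4) -> float:
    """Affine fusion of the two stream scores.

    ``lambda`` weights the segmental stream.  If one stream is missing
    (NaN — e.g. no voiced frame for F0), the weight renormalizes onto
    the available stream.
    """
    seg_ok = np.isfinite(segmental_score)
    sup_ok = np.isfinite(suprasegmental_score)
    if seg_ok and sup_ok:
        return (fusion_lambda * segmental_score
                + (1.0 - fusion_lambda) * suprasegmental_score)
    if seg_ok:
        logger.warning("suprasegmental stream missing; using segmental only")
        return float(segmental_score)
    if sup_ok:
        logger.warning("segmental stream missing; using suprasegmental only")
        return float(suprasegmental_score)
    raise ValueError("both stream scores are missing")


# ---------------------------------------------------------------------------
# intraclass correlation


def icc(ratings_a, ratings_b, confidence: float = 0.95
        ) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Returns ``(icc, ci_low, ci_high)`` with the confidence interval from
    the F-distribution method.  Absolute agreement penalizes a constant
    shift between raters, unlike consistency forms.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length rating vectors, n >= 3")
    X = np.column_stack([a, b])
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((X - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= 0:
        logger.warning("zero between-target variance; ICC undefined, returning 0")
        return 0.0, 0.0, 0.0
    value = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return float(value), float(value), float(value)

    alpha = 1.0 - confidence
    mse = max(mse, 1e-12)  # CI formulas degenerate at perfect consistency
    fj = msc / mse
    r = value
    vn = (k - 1) * (n - 1) * (k * r * fj + n * (1 + (k - 1) * r) - k * r) ** 2
    vd = ((n - 1) * k ** 2 * r ** 2 * fj ** 2
          + (n * (1 + (k - 1) * r) - k * r) ** 2)
    v = vn / vd if vd > 0 else 1.0
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(value), float(lower), float(upper)
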