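"""Speech turn segmentation and dyadic turn-taking / synchrony features.

A *speech turn* is a maximal same-speaker vocal stream containing no
internal silence of 150 ms or more; raw annotation segments closer than
that are merged.  From the merged timeline the module derives the
occupancy features (vocalization, other-noise and pause ratios for each
partner), the dyadic features (joint silence, overlap), and the
synchrony ratios: the fraction of mother vocalizations answered by an
infant vocalization onset within a 3 s window after the mother turn
ends, overall and split by motherese vs other speech.

Conventions: intervals are half-open ``[onset, offset)`` integer
milliseconds; turn merging uses strictly ``< 150 ms`` of silence while a
joint silence must be strictly ``> 150 ms`` long; the response window is
anchored at the mother-turn offset and responses are attributed to the
earliest still-open window, each mother vocalization counting at most
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io import AnnotationRecord

logger = logging.getLogger(__name__)

#: The 16 speech-turn-taking feature names, in canonical order.
STT_FEATURES = [
    "motherVocCount", "motherVocRatio", "motherNoiseRatio",
    "motherInterventionRatio", "infantVocCount", "infantVocRatio",
    "infantAtypicalRatio", "motherPauseRatio", "infantPauseRatio",
    "silenceRatio", "overlapRatio", "infantSynchronyRatio",
    "mothereseRatio", "nonMothereseRatio",
    "synchronyMothereseRatio", "synchronyNonMothereseRatio",
]


@dataclass(frozen=True)
class Turn:
    """One merged speech turn."""

    speaker: str
    category: str
    onset_ms: int
    offset_ms: int
    motherese: bool | None = None

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class SpeechTimeline:
    """Merged, per-speaker non-overlapping turns of one dyad."""

    dyad_id: str
    duration_ms: int
    turns: list[Turn] = field(default_factory=list)

    def speaker_turns(self, speaker: str, category: str | None = None) -> list[Turn]:
        return [t for t in self.turns
                if t.speaker == speaker
                and (category is None or t.category == category)]


def _merge_intervals(iv: list[tuple[int, int]],
                     gap_ms: int) -> list[tuple[int, int]]:
    """Merge intervals separated by strictly less than ``gap_ms``."""
    if not iv:
        return []
    iv = sorted(iv)
    out = [iv[0]]
    for s, e in iv[1:]:
        ps, pe = out[-1]
        if s - pe < gap_ms:  # overlap or sub-threshold silence
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def merge_turns(records: list[AnnotationRecord], gap_ms: int = 150,
                duration_ms: int | None = None,
                dyad_id: str = "") -> SpeechTimeline:
    """Build a SpeechTimeline of merged turns from raw annotations.

    Same-speaker same-category segments separated by silence strictly
    shorter than ``gap_ms`` become one turn; categories are never merged
    into each other.  Motherese labels survive merging by
    duration-weighted majority among the labeled constituents.  Residual
    cross-category overlap within a speaker is resolved by clipping the
    later turn, so per-speaker turns end up non-overlapping.
    """
    if duration_ms is None:
        duration_ms = max((r.offset_ms for r in records), default=0)
    turns: list[Turn] = []
    groups: dict[tuple[str, str], list[AnnotationRecord]] = {}
    for r in records:
        groups.setdefault((r.speaker, r.category), []).append(r)
    for (speaker, category), group in groups.items():
        merged = _merge_intervals([(r.onset_ms, r.offset_ms) for r in group],
                                  gap_ms)
        for s, e in merged:
            votes = {True: 0, False: 0}
            for r in group:
                if r.motherese is not None and r.onset_ms < e and r.offset_ms > s:
                    votes[r.motherese] += min(r.offset_ms, e) - max(r.onset_ms, s)
            if votes[True] or votes[False]:
                label = votes[True] >= votes[False]
            else:
                label = None
            turns.append(Turn(speaker, category, s, e, label))
    # resolve residual same-speaker cross-category overlap by clipping
    resolved: list[Turn] = []
    for speaker in ("mother", "infant"):
        last_end = -1
        for t in sorted((t for t in turns if t.speaker == speaker),
                        key=lambda t: (t.onset_ms, t.offset_ms)):
            s = max(t.onset_ms, last_end)
            if s < t.offset_ms:
                resolved.append(Turn(t.speaker, t.category, s, t.offset_ms,
                                     t.motherese))
                last_end = t.offset_ms
    resolved.sort(key=lambda t: (t.onset_ms, t.offset_ms, t.speaker))
    logger.info("merged %d records into %d turns", len(records), len(resolved))
    return SpeechTimeline(dyad_id=dyad_id, duration_ms=duration_ms,
                          turns=resolved)


def _union(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return _merge_intervals(iv, 1)  # gap 1 ms: merge only touching/overlapping


def _complement(iv: list[tuple[int, int]],
                duration_ms: int) -> list[tuple[int, int]]:
    out, cursor = [], 0
    for s, e in _union(iv):
        s, e = max(s, 0), min(e, duration_ms)
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < duration_ms:
        out.append((cursor, duration_ms))
    return out


def speaker_pauses(timeline: SpeechTimeline,
                   speaker: str) -> tuple[list[tuple[int, int]], float]:
    """Intervals where the speaker is not vocalizing, and their ratio.

    The pause ratio and the speaker's vocal occupancy sum to 1.
    """
    iv = [(t.onset_ms, t.offset_ms) for t in timeline.speaker_turns(speaker)]
    pauses = _complement(iv, timeline.duration_ms)
    total = sum(e - s for s, e in pauses)
    return pauses, total / timeline.duration_ms


def silences(timeline: SpeechTimeline,
             min_ms: int = 150) -> tuple[list[tuple[int, int]], float]:
    """Joint silences: neither partner speaks, strictly longer than min_ms."""
    iv = [(t.onset_ms, t.offset_ms) for t in timeline.turns]
    quiet = [(s, e) for s, e in _complement(iv, timeline.duration_ms)
             if e - s > min_ms]
    total = sum(e - s for s, e in quiet)
    return quiet, total / timeline.duration_ms


def overlap_ratio(timeline: SpeechTimeline) -> float:
    """Fraction of the interaction during which both partners vocalize.

    Vocalization overlap only: mother other-noise does not count, while
    both typical and atypical infant vocalizations do.
    """
    mother = _union([(t.onset_ms, t.offset_ms)
                     for t in timeline.speaker_turns("mother", "vocalization")])
    infant = _union([(t.onset_ms, t.offset_ms)
                     for t in timeline.speaker_turns("infant")])
    total = 0
    for ms, me in mother:
        for is_, ie in infant:
            total += max(0, min(me, ie) - max(ms, is_))
    return total / timeline.duration_ms


def _responded_flags(timeline: SpeechTimeline, window_ms: int,
                     count_atypical: bool) -> tuple[list[Turn], list[bool]]:
    """Earliest-window attribution of infant onsets to mother vocalizations."""
    mother_vocs = sorted(timeline.speaker_turns("mother", "vocalization"),
                         key=lambda t: t.offset_ms)
    cats = ("vocalization", "atypical_vocalization") if count_atypical \
        else ("vocalization",)
    onsets = sorted(t.onset_ms for t in timeline.speaker_turns("infant")
                    if t.category in cats)
    used = [False] * len(onsets)
    flags = []
    for mv in mother_vocs:
        hit = False
        for i, on in enumerate(onsets):
            if used[i] or on <= mv.offset_ms:
                continue
            if on > mv.offset_ms + window_ms:
                break
            used[i] = True
            hit = True
            break
        flags.append(hit)
    return mother_vocs, flags


def synchrony_ratio(timeline: SpeechTimeline, window_ms: int = 3000,
                    subset: str = "all",
                    count_atypical: bool = False) -> float:
    """Fraction of (subset) mother vocalizations answered within the window.

    A mother vocalization counts as answered iff an infant vocalization
    onset falls strictly inside ``(offset, offset + window_ms]``.
    ``subset`` restricts the denominator to ``motherese`` or
    ``non_motherese`` mother turns; NaN when the subset is empty.
    """
    mother_vocs, flags = _responded_flags(timeline, window_ms, count_atypical)
    if subset == "all":
        keep = [True] * len(mother_vocs)
    elif subset == "motherese":
        keep = [t.motherese is True for t in mother_vocs]
    elif subset == "non_motherese":
        keep = [t.motherese is False for t in mother_vocs]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    n = sum(keep)
    if n == 0:
        return float("nan")
    return sum(f for f, k in zip(flags, keep) if k) / n


def stt_features(timeline: SpeechTimeline,
                 config: RunConfig | None = None) -> dict[str, float]:
    """The 16-element speech-turn-taking feature vector of one dyad.

    Motherese-dependent features are NaN when no turn carries a
    motherese label.  The mother intervention ratio pools vocalization
    and other-noise time.
    """
    config = config or RunConfig()
    if timeline.duration_ms <= 0:
        raise ValueError("zero-duration timeline")
    dur = timeline.duration_ms

    def cat_time(speaker: str, category: str) -> int:
        return sum(t.duration_ms
                   for t in timeline.speaker_turns(speaker, category))

    _, mother_pause = speaker_pauses(timeline, "mother")
    _, infant_pause = speaker_pauses(timeline, "infant")
    _, silence = silences(timeline, config.silence_min_ms)

    mother_vocs = timeline.speaker_turns("mother", "vocalization")
    labeled = [t for t in mother_vocs if t.motherese is not None]
    if labeled:
        motherese_ratio = sum(t.duration_ms for t in labeled
                              if t.motherese) / dur
        non_motherese_ratio = sum(t.duration_ms for t in labeled
                                  if not t.motherese) / dur
    else:
        motherese_ratio = non_motherese_ratio = float("nan")

    feats = {
        "motherVocCount": float(len(mother_vocs)),
        "motherVocRatio": cat_time("mother", "vocalization") / dur,
        "motherNoiseRatio": cat_time("mother", "other_noise") / dur,
        "motherInterventionRatio":
            (cat_time("mother", "vocalization")
             + cat_time("mother", "other_noise")) / dur,
        "infantVocCount": float(len(timeline.speaker_turns(
            "infant", "vocalization"))),
        "infantVocRatio": cat_time("infant", "vocalization") / dur,
        "infantAtypicalRatio": cat_time("infant", "atypical_vocalization") / dur,
        "motherPauseRatio": mother_pause,
        "infantPauseRatio": infant_pause,
        "silenceRatio": silence,
        "overlapRatio": overlap_ratio(timeline),
        "infantSynchronyRatio": synchrony_ratio(
            timeline, config.synchrony_window_ms, "all",
            config.count_atypical_as_response),
        "mothereseRatio": motherese_ratio,
        "nonMothereseRatio": non_motherese_ratio,
        "synchronyMothereseRatio": synchrony_ratio(
            timeline, config.synchrony_window_ms, "motherese",
            config.count_atypical_as_response),
        "synchronyNonMothereseRatio": synchrony_ratio(
            timeline, config.synchrony_window_ms, "non_motherese",
            config.count_atypical_as_response),
    }
    assert list(feats) == STT_FEATURES
    return feats
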