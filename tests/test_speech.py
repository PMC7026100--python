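import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadkit.config import RunConfig
from dyadkit.io import AnnotationRecord
from dyadkit.speech import (STT_FEATURES, merge_turns, overlap_ratio,
                            silences, speaker_pauses, stt_features,
                            synchrony_ratio)


def rec(speaker, onset, offset, category="vocalization", motherese=None):
    return AnnotationRecord(speaker, category, onset, offset,
                            motherese=motherese)


def brute_force_merge(intervals, gap_ms):
    """Transitive closure of the 'closer than gap' merge relation."""
    intervals = [list(iv) for iv in sorted(intervals)]
    changed = True
    while changed:
        changed = False
        for i in range(len(intervals) - 1):
            a, b = intervals[i], intervals[i + 1]
            if b[0] - a[1] < gap_ms:
                intervals[i] = [a[0], max(a[1], b[1])]
                del intervals[i + 1]
                changed = True
                break
    return [tuple(iv) for iv in intervals]


class TestMergeTurns:

    def test_sub_threshold_gap_merges(self):
        tl = merge_turns([rec("mother", 0, 1000), rec("mother", 1100, 2000)],
                         gap_ms=150, duration_ms=3000)
        assert [(t.onset_ms, t.offset_ms) for t in tl.turns] == [(0, 2000)]

    def test_gap_of_exactly_150_stays_split(self):
        tl = merge_turns([rec("mother", 0, 1000), rec("mother", 1150, 2000)],
                         gap_ms=150, duration_ms=3000)
        assert len(tl.turns) == 2

    def test_categories_never_merge(self):
        tl = merge_turns([rec("mother", 0, 1000),
                          rec("mother", 1050, 2000, "other_noise")],
                         duration_ms=3000)
        assert len(tl.turns) == 2

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 800)),
                    min_size=1, max_size=30))
    def test_matches_transitive_closure_oracle(self, soup):
        records = [rec("infant", s, s + d) for s, d in soup]
        tl = merge_turns(records, gap_ms=150, duration_ms=10_000)
        got = [(t.onset_ms, t.offset_ms) for t in tl.turns]
        assert got == brute_force_merge([(s, s + d) for s, d in soup], 150)

    def test_motherese_label_survives_merge(self):
        tl = merge_turns([rec("mother", 0, 1000, motherese=True),
                          rec("mother", 1050, 1400, motherese=True)],
                         duration_ms=2000)
        assert tl.turns[0].motherese is True


class TestSpeakerPauses:

    def test_silent_speaker_full_pause(self):
        tl = merge_turns([rec("mother", 0, 1000)], duration_ms=5000)
        intervals, ratio = speaker_pauses(tl, "infant")
        assert intervals == [(0, 5000)]
        assert ratio == 1.0

    def test_always_speaking_no_pause(self):
        tl = merge_turns([rec("mother", 0, 5000)], duration_ms=5000)
        _, ratio = speaker_pauses(tl, "mother")
        assert ratio == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        records = [rec("mother", int(s), int(s) + int(d))
                   for s, d in zip(rng.integers(0, 9000, 15),
                                   rng.integers(1, 900, 15))]
        tl = merge_turns(records, duration_ms=10_000)
        _, pause_ratio = speaker_pauses(tl, "mother")
        vocal = sum(t.duration_ms for t in tl.speaker_turns("mother"))
        assert pause_ratio + vocal / 10_000 == pytest.approx(1.0)


class TestSilences:

    def test_handover_without_silence(self):
        tl = merge_turns([rec("mother", 0, 10_000),
                          rec("infant", 10_000, 20_000)],
                         duration_ms=20_000)
        intervals, ratio = silences(tl)
        assert intervals == [] and ratio == 0.0

    def test_tail_silence_detected(self):
        tl = merge_turns([rec("mother", 0, 15_000)], duration_ms=20_000)
        intervals, ratio = silences(tl)
        assert intervals == [(15_000, 20_000)]
        assert ratio == pytest.approx(0.25)

    def test_short_joint_silence_excluded(self):
        tl = merge_turns([rec("mother", 0, 1000), rec("infant", 1100, 2000)],
                         duration_ms=2000)
        intervals, _ = silences(tl, min_ms=150)
        assert intervals == []


class TestOverlap:

    def test_quarter_overlap(self):
        tl = merge_turns([rec("mother", 0, 10_000), rec("infant", 5000, 15_000)],
                         duration_ms=20_000)
        assert overlap_ratio(tl) == pytest.approx(0.25)

    def test_disjoint_turns_zero(self):
        tl = merge_turns([rec("mother", 0, 1000), rec("infant", 2000, 3000)],
                         duration_ms=4000)
        assert overlap_ratio(tl) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_ms_occupancy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dur = 5000
        records = []
        for speaker in ("mother", "infant"):
            for s, d in zip(rng.integers(0, dur - 100, 8),
                            rng.integers(1, 600, 8)):
                records.append(rec(speaker, int(s), min(int(s + d), dur)))
        tl = merge_turns(records, duration_ms=dur)
        m = np.zeros(dur, dtype=bool)
        i = np.zeros(dur, dtype=bool)
        for t in tl.turns:
            (m if t.speaker == "mother" else i)[t.onset_ms:t.offset_ms] = True
        assert overlap_ratio(tl) == pytest.approx(np.mean(m & i) * dur / dur)


class TestSynchrony:

    def test_window_enumeration(self):
        # mother turns ending at 1, 5, 9 s; infant onsets at 2 and 20 s
        records = [rec("mother", 0, 1000), rec("mother", 4000, 5000),
                   rec("mother", 8000, 9000),
                   rec("infant", 2000, 2500), rec("infant", 20_000, 20_500)]
        tl = merge_turns(records, duration_ms=30_000)
        assert synchrony_ratio(tl, 3000) == pytest.approx(1 / 3)

    def test_all_answered(self):
        records = [rec("mother", 0, 1000), rec("infant", 1500, 2000),
                   rec("mother", 5000, 6000), rec("infant", 6100, 6500)]
        tl = merge_turns(records, duration_ms=10_000)
        assert synchrony_ratio(tl, 3000) == 1.0

    def test_zero_window_zero_ratio(self):
        records = [rec("mother", 0, 1000), rec("infant", 1500, 2000)]
        tl = merge_turns(records, duration_ms=5000)
        assert synchrony_ratio(tl, 0) == 0.0

    def test_overlapping_infant_onset_does_not_count(self):
        records = [rec("mother", 0, 2000), rec("infant", 1000, 1500)]
        tl = merge_turns(records, duration_ms=5000)
        assert synchrony_ratio(tl, 3000) == 0.0

    def test_one_response_cannot_answer_two_mothers(self):
        records = [rec("mother", 0, 1000), rec("mother", 1200, 2000),
                   rec("infant", 2500, 2800)]
        tl = merge_turns(records, duration_ms=6000)
        # the single onset is attributed to the earliest open window
        assert synchrony_ratio(tl, 3000) == pytest.approx(0.5)

    def test_empty_subset_undefined(self):
        records = [rec("mother", 0, 1000)]
        tl = merge_turns(records, duration_ms=5000)
        assert np.isnan(synchrony_ratio(tl, subset="motherese"))

    def test_all_subset_between_labeled_subsets(self):
        rng = np.random.default_rng(1)
        records = []
        t = 0
        for k in range(40):
            t += int(rng.integers(500, 3000))
            records.append(rec("mother", t, t + 800,
                               motherese=bool(k % 2)))
            if rng.random() < 0.5:
                records.append(rec("infant", t + 900, t + 1400))
            t += 1000
        tl = merge_turns(records, duration_ms=t + 5000)
        all_r = synchrony_ratio(tl)
        m = synchrony_ratio(tl, subset="motherese")
        nm = synchrony_ratio(tl, subset="non_motherese")
        assert min(m, nm) - 1e-12 <= all_r <= max(m, nm) + 1e-12


class TestSttFeatures:

    def test_empty_timeline(self):
        from dyadkit.speech import SpeechTimeline
        tl = SpeechTimeline(dyad_id="d", duration_ms=60_000, turns=[])
        feats = stt_features(tl)
        assert feats["motherVocCount"] == 0
        assert feats["silenceRatio"] == 1.0
        assert np.isnan(feats["infantSynchronyRatio"])

    def test_constructed_occupancy(self):
        dur = 100_000
        records = [
            rec("mother", 0, 25_000),                  # 25% voc
            rec("mother", 30_000, 35_000, "other_noise"),  # 5% noise
            rec("infant", 20_000, 40_000),             # 20% voc, 5% overlap
        ]
        tl = merge_turns(records, duration_ms=dur)
        feats = stt_features(tl)
        assert feats["motherVocRatio"] == pytest.approx(0.25)
        assert feats["motherNoiseRatio"] == pytest.approx(0.05)
        assert feats["motherInterventionRatio"] == pytest.approx(0.30)
        assert feats["infantVocRatio"] == pytest.approx(0.20)
        assert feats["overlapRatio"] == pytest.approx(0.05)

    def test_vector_schema(self):
        tl = merge_turns([rec("mother", 0, 1000, motherese=True),
                          rec("infant", 1500, 2500)], duration_ms=10_000)
        feats = stt_features(tl)
        assert list(feats) == STT_FEATURES
        assert len(feats) == 16

    def test_motherese_fields_missing_when_unlabeled(self):
        tl = merge_turns([rec("mother", 0, 1000)], duration_ms=5000)
        feats = stt_features(tl)
        assert np.isnan(feats["mothereseRatio"])
        assert np.isnan(feats["synchronyMothereseRatio"])

    @pytest.mark.parametrize("seed", range(4))
    def test_occupancy_conservation(self, seed):
        from dyadkit.synthetic import TimelineParams, make_timeline
        records = make_timeline(TimelineParams(), 120_000, seed=seed)
        tl = merge_turns(records, duration_ms=120_000)
        feats = stt_features(tl)
        assert feats["motherVocRatio"] + feats["motherNoiseRatio"] \
            + feats["motherPauseRatio"] == pytest.approx(1.0)
        assert feats["infantVocRatio"] + feats["infantAtypicalRatio"] \
            + feats["infantPauseRatio"] == pytest.approx(1.0)

    def test_zero_duration_rejected(self):
        from dyadkit.speech import SpeechTimeline
        with pytest.raises(ValueError):
            stt_features(SpeechTimeline("d", 0, []))
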