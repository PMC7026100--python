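"""End-to-end glue: dyads -> multimodal feature table -> classification."""

from __future__ import annotations

import pandas as pd

from .config import RunConfig
from .motion_features import MOTION_FEATURES, motion_features, select_window
from .outcome import DyadOutcomeModel, DyadOutcomeResults
from .speech import STT_FEATURES, merge_turns, stt_features
from .synthetic import DyadRecord

#: Modality tags in report style, per feature.
MODALITY = {**{f: "Audio" for f in STT_FEATURES},
            **{f: "Video, infant" for f in MOTION_FEATURES}}
for _f in ("infantSynchronyRatio", "synchronyMothereseRatio",
           "synchronyNonMothereseRatio"):
    MODALITY[_f] = "Audio, synchrony"
for _f in ("infantVocCount", "infantVocRatio", "infantAtypicalRatio",
           "infantPauseRatio"):
    MODALITY[_f] = "Audio, infant"
for _f in ("motherVocCount", "motherVocRatio", "motherNoiseRatio",
           "motherInterventionRatio", "motherPauseRatio", "mothereseRatio",
           "nonMothereseRatio"):
    MODALITY[_f] = "Audio, mother"


def dyad_features(dyad: DyadRecord, config: RunConfig | None = None
                  ) -> dict[str, float]:
    """Extract the 16 speech + 21 hand-movement features of one dyad."""
    config = config or RunConfig()
    duration_ms = max((r.offset_ms for r in dyad.timeline), default=0)
    timeline = merge_turns(dyad.timeline, config.turn_gap_ms,
                           duration_ms=max(duration_ms, 1),
                           dyad_id=dyad.dyad_id)
    feats = dict(stt_features(timeline, config))
    window = select_window(dyad.trajectory)
    feats.update(motion_features(window, config))
    return feats


def cohort_feature_table(cohort: list[DyadRecord],
                         config: RunConfig | None = None
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Features (dyads x 37) and group labels for a generated cohort."""
    rows = {d.dyad_id: dyad_features(d, config) for d in cohort}
    table = pd.DataFrame.from_dict(rows, orient="index")
    labels = pd.Series({d.dyad_id: d.group for d in cohort}, name="group")
    return table, labels.reindex(table.index)


def classify_cohort(cohort: list[DyadRecord], mode: str = "ws_vs_td",
                    config: RunConfig | None = None) -> DyadOutcomeResults:
    """Run the full outcome classification on a generated cohort.

    ``mode="ws_vs_td"`` pools WS- and WS+ into one WS class against TD;
    ``mode="wsplus_vs_wsminus"`` contrasts the two WS subgroups.
    """
    table, labels = cohort_feature_table(cohort, config)
    if mode == "ws_vs_td":
        labels = labels.map(lambda g: "TD" if g == "TD" else "WS")
    elif mode == "wsplus_vs_wsminus":
        keep = labels != "TD"
        table, labels = table.loc[keep], labels.loc[keep]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    model = DyadOutcomeModel(table, labels, config, modality=MODALITY)
    return model.fit()
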