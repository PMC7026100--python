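"""Readers and writers for annotation timelines, trajectories, and reports.

On-disk formats
---------------
* annotation TSV: columns ``speaker  category  onset_ms  offset_ms
  [motherese]`` — the canonical format; times are integer milliseconds,
  intervals half-open ``[onset, offset)``.
* EAF subset (read-only): a minimal slice of ELAN's XML — one tier per
  speaker, annotation value = category; full EAF semantics are out of
  scope.
* trajectory CSV: columns ``frame x y visible``; invisible frames carry
  empty coordinates.
* report JSON: confusion matrix, accuracy and features ranked by |r|.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracking import Trajectory

logger = logging.getLogger(__name__)

SPEAKERS = ("mother", "infant")
CATEGORIES = ("vocalization", "other_noise", "atypical_vocalization")


@dataclass(frozen=True)
class AnnotationRecord:
    """One labeled vocal segment of the dyadic interaction.

    Mothers produce ``vocalization`` (speech, laugh, singing, animal
    sounds) or ``other_noise`` (claps, finger snaps, mouth noise);
    infants produce ``vocalization`` (babbling, laugh, cry) or
    ``atypical_vocalization``.  ``motherese`` optionally labels mother
    vocalizations as infant-directed speech (None = unlabeled).
    """

    speaker: str
    category: str
    onset_ms: int
    offset_ms: int
    motherese: bool | None = None

    def __post_init__(self) -> None:
        if self.speaker not in SPEAKERS:
            raise ValueError(f"unknown speaker {self.speaker!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be non-negative")
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset_ms must exceed onset_ms")
        if self.category == "other_noise" and self.speaker != "mother":
            raise ValueError("other_noise is a mother-only category")
        if self.category == "atypical_vocalization" and self.speaker != "infant":
            raise ValueError("atypical_vocalization is an infant-only category")
        if self.motherese is not None and not (
                self.speaker == "mother" and self.category == "vocalization"):
            raise ValueError("motherese labels apply only to mother vocalizations")

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


_TSV_HEADER = ["speaker", "category", "onset_ms", "offset_ms", "motherese"]


def read_annotations(path: str | Path,
                     dialect: str = "tsv") -> list[AnnotationRecord]:
    """Read an annotation timeline, sorted by onset.

    ``dialect`` is ``"tsv"`` (canonical) or ``"eaf_subset"``.
    Overlapping same-speaker raw segments are allowed here; they are
    merged downstream during turn segmentation.
    """
    if dialect == "tsv":
        records = _read_tsv(Path(path))
    elif dialect == "eaf_subset":
        records = _read_eaf_subset(Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    records.sort(key=lambda r: (r.onset_ms, r.offset_ms, r.speaker, r.category))
    logger.info("read %d annotation records from %s", len(records), path)
    return records


def _read_tsv(path: Path) -> list[AnnotationRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "speaker":
                continue  # header
            if len(fields) not in (4, 5):
                raise ValueError(
                    f"{path}:{lineno}: expected 4 or 5 tab-separated fields, "
                    f"got {len(fields)}")
            try:
                motherese = None
                if len(fields) == 5 and fields[4] != "":
                    motherese = {"true": True, "false": False}[fields[4].lower()]
                records.append(AnnotationRecord(
                    speaker=fields[0], category=fields[1],
                    onset_ms=int(fields[2]), offset_ms=int(fields[3]),
                    motherese=motherese))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def _read_eaf_subset(path: Path) -> list[AnnotationRecord]:
    """Minimal ELAN EAF reader: tier name -> speaker, value -> category."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed EAF XML: {exc}") from exc
    root = tree.getroot()
    slots = {
        ts.get("TIME_SLOT_ID"): int(ts.get("TIME_VALUE"))
        for ts in root.iter("TIME_SLOT")
    }
    records = []
    for tier in root.iter("TIER"):
        speaker = tier.get("TIER_ID", "").lower()
        if speaker not in SPEAKERS:
            continue
        for ann in tier.iter("ALIGNABLE_ANNOTATION"):
            value_el = ann.find("ANNOTATION_VALUE")
            category = (value_el.text or "").strip() if value_el is not None else ""
            records.append(AnnotationRecord(
                speaker=speaker, category=category,
                onset_ms=slots[ann.get("TIME_SLOT_REF1")],
                offset_ms=slots[ann.get("TIME_SLOT_REF2")]))
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path,
                      dialect: str = "tsv") -> None:
    """Write records so that ``read_annotations`` round-trips exactly."""
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for r in records:
                m = "" if r.motherese is None else str(r.motherese).lower()
                fh.write(f"{r.speaker}\t{r.category}\t{r.onset_ms}\t"
                         f"{r.offset_ms}\t{m}\n")
    elif dialect == "eaf_subset":
        _write_eaf_subset(list(records), Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_eaf_subset(records: Sequence[AnnotationRecord], path: Path) -> None:
    root = ET.Element("ANNOTATION_DOCUMENT")
    order = ET.SubElement(root, "TIME_ORDER")
    slot_of: dict[int, str] = {}

    def slot(t: int) -> str:
        if t not in slot_of:
            sid = f"ts{len(slot_of) + 1}"
            slot_of[t] = sid
            ET.SubElement(order, "TIME_SLOT",
                          TIME_SLOT_ID=sid, TIME_VALUE=str(t))
        return slot_of[t]

    aid = 0
    for speaker in SPEAKERS:
        tier = ET.SubElement(root, "TIER", TIER_ID=speaker)
        for r in records:
            if r.speaker != speaker:
                continue
            aid += 1
            ann = ET.SubElement(tier, "ANNOTATION")
            al = ET.SubElement(ann, "ALIGNABLE_ANNOTATION",
                               ANNOTATION_ID=f"a{aid}",
                               TIME_SLOT_REF1=slot(r.onset_ms),
                               TIME_SLOT_REF2=slot(r.offset_ms))
            ET.SubElement(al, "ANNOTATION_VALUE").text = r.category
    ET.ElementTree(root).write(path, encoding="unicode",
                               xml_declaration=True)


def read_trajectory(path: str | Path, fps: float = 25.0) -> Trajectory:
    """Read a trajectory CSV (frame, x, y, visible).

    Invisible frames may have empty coordinate cells; duplicate frame
    indices are an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "x", "y", "visible"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trajectory CSV needs columns {sorted(required)}")
    frames = df["frame"].to_numpy(dtype=int)
    if len(np.unique(frames)) != len(frames):
        raise ValueError(f"{path}: duplicate frame index")
    visible = df["visible"].astype(str).str.lower().isin(["true", "1"]).to_numpy()
    x = pd.to_numeric(df["x"], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy(dtype=float)
    x[~visible] = np.nan
    y[~visible] = np.nan
    return Trajectory(fps=fps, frames=frames, x=x, y=y, visible=visible)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("frame,x,y,visible\n")
        for f, x, y, v in zip(traj.frames, traj.x, traj.y, traj.visible):
            if v:
                fh.write(f"{f},{float(x)!r},{float(y)!r},true\n")
            else:
                fh.write(f"{f},,,false\n")


def write_report(classification_result, feature_correlations,
                 path: str | Path) -> dict:
    """Write the classification report JSON.

    Layout: the confusion matrix with its
    accuracy, and the contributing features ranked by the magnitude of
    their point-biserial correlation with the class, each with its
    modality tag, r and p.  Byte-identical for identical inputs.
    """
    ranked = sorted(feature_correlations, key=lambda fc: -abs(fc["r"]))
    report = {
        "confusion_matrix": [[int(c) for c in row]
                             for row in classification_result.confusion_matrix],
        "accuracy": float(classification_result.accuracy),
        "accuracy_percent": round(100.0 * classification_result.accuracy, 2),
        "classes": list(classification_result.classes),
        "n": int(np.sum(classification_result.confusion_matrix)),
        "features": [
            {"feature": fc["feature"],
             "modality": fc.get("modality", ""),
             "r": round(float(fc["r"]), 4),
             "p": float(f"{fc['p']:.3g}")}
            for fc in ranked
        ],
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
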