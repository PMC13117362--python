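"""Data model and I/O for longitudinal clinical-note corpora.

A corpus is a JSON-lines file of notes (one object per line with ``note_id``,
``patient_id``, ``timestamp``, ``sections``, ``text``) plus a patient-level
label table (TSV, ``patient_id<TAB>label``, optional ``diagnosis_date``).
Patients are the atomic unit everywhere: ordering, splitting and resampling
never cross a patient boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLASSES = ("Normal", "MCI", "AD")
SECTION_NAMES = ("history", "medications", "assessment")
SPLITS = ("train", "val", "test")


class CorpusError(ValueError):
    """Fatal corpus contract violation."""


def parse_timestamp(value: str) -> datetime:
    """Parse an ISO-8601 timestamp; naive stamps are taken as UTC."""
    ts = datetime.fromisoformat(str(value))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass
class Note:
    """One timestamped, section-tagged clinical document."""

    note_id: str
    patient_id: str
    timestamp: datetime
    sections: dict[str, str] = field(default_factory=dict)
    text: str = ""
    tokens: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.timestamp, str):
            self.timestamp = parse_timestamp(self.timestamp)
        for name in self.sections:
            if name not in SECTION_NAMES and name != "other":
                raise CorpusError(
                    f"note {self.note_id}: unknown section {name!r} "
                    f"(expected one of {SECTION_NAMES} or 'other')"
                )


@dataclass
class PatientRecord:
    """A patient's time-ordered note sequence plus a patient-level label."""

    patient_id: str
    notes: list[Note]
    label: str
    diagnosis_date: datetime | None = None
    synthetic_of: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in CLASSES:
            raise CorpusError(
                f"patient {self.patient_id}: unknown label {self.label!r}"
            )
        self.notes = sort_notes(self.notes)

    @property
    def span_days(self) -> int:
        if len(self.notes) < 2:
            return 0
        return (self.notes[-1].timestamp - self.notes[0].timestamp).days


@dataclass
class SplitAssignment:
    """Patient -> split mapping with a per-class stratification report."""

    assignment: dict[str, str]
    report: dict[str, dict[str, int]]  # class -> split -> n patients

    def patients(self, split: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def subset(self, records: list[PatientRecord], split: str) -> list[PatientRecord]:
        return [r for r in records if self.assignment.get(r.patient_id) == split]


def sort_notes(notes: list[Note]) -> list[Note]:
    """Ascending timestamp; ties broken by lexicographic note_id."""
    return sorted(notes, key=lambda n: (n.timestamp, n.note_id))


# ---------------------------------------------------------------------------
# readers / writers


def read_labels(labels_path) -> pd.DataFrame:
    df = pd.read_csv(labels_path, sep="\t", dtype=str)
    if "patient_id" not in df.columns or "label" not in df.columns:
        raise CorpusError(f"{labels_path}: labels TSV needs patient_id and label columns")
    bad = sorted(set(df["label"]) - set(CLASSES))
    if bad:
        raise CorpusError(f"{labels_path}: unknown label string(s) {bad}")
    return df


def read_corpus(notes_path, labels_path) -> list[PatientRecord]:
    """Read a JSONL note corpus and patient label table into records.

    Malformed JSON lines are dropped and counted (logged); an unparseable
    timestamp or a note whose patient is missing from the label table is a
    hard error naming the offending line/patient.
    """
    labels = read_labels(labels_path)
    label_of = dict(zip(labels["patient_id"], labels["label"]))
    diag_of = {}
    if "diagnosis_date" in labels.columns:
        for pid, d in zip(labels["patient_id"], labels["diagnosis_date"]):
            if isinstance(d, str) and d:
                diag_of[pid] = parse_timestamp(d)

    notes_by_patient: dict[str, list[Note]] = {}
    dropped = 0
    with open(notes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError:
                dropped += 1
                continue
            try:
                ts = parse_timestamp(obj["timestamp"])
            except (KeyError, ValueError) as exc:
                raise CorpusError(f"{notes_path} line {lineno}: bad timestamp ({exc})") from exc
            pid = str(obj["patient_id"])
            if pid not in label_of:
                raise CorpusError(
                    f"{notes_path} line {lineno}: patient {pid!r} absent from labels table"
                )
            note = Note(
                note_id=str(obj["note_id"]),
                patient_id=pid,
                timestamp=ts,
                sections=dict(obj.get("sections", {})),
                text=str(obj.get("text", "")),
            )
            notes_by_patient.setdefault(pid, []).append(note)
    if dropped:
        log.warning("read_corpus: dropped %d malformed line(s)", dropped)

    records = [
        PatientRecord(
            patient_id=pid,
            notes=notes,
            label=label_of[pid],
            diagnosis_date=diag_of.get(pid),
        )
        for pid, notes in notes_by_patient.items()
    ]
    records.sort(key=lambda r: r.patient_id)
    for r in records:
        r.meta["dropped_lines"] = dropped
    return records


def write_corpus(records: list[PatientRecord], notes_path, labels_path) -> None:
    with open(notes_path, "w", encoding="utf-8") as fh:
        for record in records:
            for note in record.notes:
                fh.write(json.dumps({
                    "note_id": note.note_id,
                    "patient_id": note.patient_id,
                    "timestamp": note.timestamp.isoformat(),
                    "sections": note.sections,
                    "text": note.text,
                }) + "\n")
    rows = []
    for record in records:
        row = {"patient_id": record.patient_id, "label": record.label}
        if record.diagnosis_date is not None:
            row["diagnosis_date"] = record.diagnosis_date.isoformat()
        rows.append(row)
    pd.DataFrame(rows).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# splitting


def split_patients(
    records: list[PatientRecord],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified patient-level 70/15/15 split with zero cross-split leakage.

    Within each class, patients are shuffled (seeded) and allocated by the
    largest-remainder method, so per-class split counts differ from the exact
    fractions by at most one patient — except for very small classes, where
    guaranteeing that every split contains every class can force one extra
    patient of deviation.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise CorpusError(f"split fractions must sum to 1, got {fractions}")
    by_class: dict[str, list[str]] = {c: [] for c in CLASSES}
    for r in records:
        by_class[r.label].append(r.patient_id)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    report: dict[str, dict[str, int]] = {}
    for cls in CLASSES:
        pids = sorted(by_class[cls])
        if not pids:
            continue
        if len(pids) < len(SPLITS):
            raise CorpusError(
                f"class {cls!r} has {len(pids)} patient(s); need at least {len(SPLITS)}"
            )
        rng.shuffle(pids)
        n = len(pids)
        base = [int(np.floor(f * n)) for f in fractions]
        rem = n - sum(base)
        # give leftover patients to the splits with the largest fractional part
        fracs = [(f * n - b, i) for i, (f, b) in enumerate(zip(fractions, base))]
        for _, i in sorted(fracs, key=lambda t: (-t[0], t[1]))[:rem]:
            base[i] += 1
        # guarantee every split sees every class
        for i in range(len(SPLITS)):
            while base[i] == 0:
                j = int(np.argmax(base))
                base[j] -= 1
                base[i] += 1
        off = 0
        counts = {}
        for split, k in zip(SPLITS, base):
            for pid in pids[off:off + k]:
                assignment[pid] = split
            counts[split] = k
            off += k
        report[cls] = counts
    return SplitAssignment(assignment=assignment, report=report)


def write_splits(split: SplitAssignment, path) -> None:
    pd.DataFrame(
        [{"patient_id": p, "split": s} for p, s in sorted(split.assignment.items())]
    ).to_csv(path, sep="\t", index=False)


def read_splits(path) -> SplitAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SplitAssignment(
        assignment=dict(zip(df["patient_id"], df["split"])), report={}
    )


# ---------------------------------------------------------------------------
# eligibility and temporal truncation


def filter_eligible(
    records: list[PatientRecord], min_notes: int = 3, min_span_days: int = 0
) -> list[PatientRecord]:
    """Configurable longitudinal eligibility rule (minimum encounters/span)."""
    return [
        r for r in records
        if len(r.notes) >= min_notes and r.span_days >= min_span_days
    ]


def truncate_before_label(record: PatientRecord, min_gap_days: int) -> PatientRecord:
    """Drop notes within ``min_gap_days`` of the reference diagnosis date.

    The reference date defaults to the final note's date when no explicit
    diagnosis date is on the record. The result may be empty; that is legal
    and flagged in ``meta['truncated_empty']``.
    """
    if not record.notes:
        return record
    reference = record.diagnosis_date or record.notes[-1].timestamp
    kept = [n for n in record.notes if (reference - n.timestamp).days >= min_gap_days]
    out = PatientRecord(
        patient_id=record.patient_id,
        notes=kept,
        label=record.label,
        diagnosis_date=record.diagnosis_date,
        synthetic_of=record.synthetic_of,
        meta=dict(record.meta),
    )
    out.meta["truncated_empty"] = not kept
    if not kept:
        log.warning("truncate_before_label: patient %s left with no notes", record.patient_id)
    return out
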