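"""Corpus records and CSV/JSONL readers and writers.

A corpus is a flat table of free-text notes with the schema
``patient_id, note_id, note_type (clinical|pathology), note_date, text``.
Text is preserved byte-exact on read (no whitespace normalization) so that
mention spans refer to the original characters.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .patient_assembly import PatientGleasonRecord

NOTE_TYPES = ("clinical", "pathology")
REQUIRED_COLUMNS = ("patient_id", "note_id", "note_type", "text")


class SchemaError(ValueError):
    """A corpus file does not match the documented schema."""


@dataclass
class Note:
    """One free-text document."""

    patient_id: str
    note_id: str
    note_type: str
    text: str
    note_date: Optional[str] = None


#: alias used by the I/O layer
CorpusRecord = Note


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise SchemaError(f"unknown corpus format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    raise SchemaError(f"cannot infer corpus format from {path!r}; pass format=")


def _validate_row(row: dict, rownum: int) -> Note:
    for col in REQUIRED_COLUMNS:
        if col not in row or row[col] in (None, ""):
            raise SchemaError(f"row {rownum}: missing required column {col!r}")
    if row["note_type"] not in NOTE_TYPES:
        raise SchemaError(
            f"row {rownum}: unknown note_type {row['note_type']!r}; "
            f"expected one of {NOTE_TYPES}"
        )
    date = row.get("note_date") or None
    return Note(
        patient_id=str(row["patient_id"]),
        note_id=str(row["note_id"]),
        note_type=row["note_type"],
        text=str(row["text"]),
        note_date=None if date is None else str(date),
    )


def read_corpus(path, fmt: Optional[str] = None) -> list[Note]:
    """Read and validate a note corpus from CSV or JSONL.

    Raises :class:`SchemaError` naming the offending row for missing columns,
    unknown note types, or duplicate note ids.
    """
    fmt = _infer_format(path, fmt)
    notes: list[Note] = []
    if fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                rows = []
            else:
                missing = set(REQUIRED_COLUMNS) - set(reader.fieldnames)
                if missing:
                    raise SchemaError(f"missing required column(s) {sorted(missing)}")
                rows = list(reader)
        for i, row in enumerate(rows, start=2):  # header is line 1
            notes.append(_validate_row(row, i))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"row {i}: invalid JSON: {exc}") from exc
                if not isinstance(row, dict):
                    raise SchemaError(f"row {i}: expected a JSON object")
                notes.append(_validate_row(row, i))
    seen: dict[str, int] = {}
    for i, note in enumerate(notes):
        if note.note_id in seen:
            raise SchemaError(
                f"duplicate note_id {note.note_id!r} (records "
                f"{seen[note.note_id]} and {i})"
            )
        seen[note.note_id] = i
    return notes


def write_corpus(notes: Iterable[Note], path, fmt: Optional[str] = None) -> None:
    fmt = _infer_format(path, fmt)
    fields = ["patient_id", "note_id", "note_type", "note_date", "text"]
    rows = [
        {
            "patient_id": n.patient_id,
            "note_id": n.note_id,
            "note_type": n.note_type,
            "note_date": n.note_date or "",
            "text": n.text,
        }
        for n in notes
    ]
    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerows(rows)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


# --- structured output ------------------------------------------------------

_RESULT_FIELDS = [
    "patient_id",
    "surgery_P",
    "surgery_S",
    "surgery_T",
    "surgery_status",
    "surgery_triage",
    "surgery_reasons",
    "biopsy_P",
    "biopsy_S",
    "biopsy_T",
    "biopsy_status",
    "biopsy_triage",
    "biopsy_reasons",
]


def _score_cells(triple) -> tuple[str, str, str, str]:
    if triple is None:
        return "", "", "", "not_found"
    p, s, t = triple.astuple()
    fmt = lambda v: "" if v is None else str(v)
    return fmt(p), fmt(s), fmt(t), "found"


def write_records_csv(records: Iterable[PatientGleasonRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESULT_FIELDS)
        for r in records:
            sp, ss, st, s_status = _score_cells(r.surgery_score)
            bp, bs, bt, b_status = _score_cells(r.biopsy_score)
            writer.writerow(
                [
                    r.patient_id,
                    sp,
                    ss,
                    st,
                    s_status,
                    r.surgery_triage.value,
                    ";".join(r.surgery_reasons),
                    bp,
                    bs,
                    bt,
                    b_status,
                    r.biopsy_triage.value,
                    ";".join(r.biopsy_reasons),
                ]
            )


def read_records_csv(path) -> dict:
    """Per-task view of a results table: (patient_id, specimen) -> dict.

    Each value holds ``triple`` (a (P, S, T) tuple or None for not_found)
    and ``triage``.
    """
    tasks = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_RESULT_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"results file missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            for st in ("surgery", "biopsy"):
                if row[f"{st}_status"] == "found":
                    cells = (row[f"{st}_P"], row[f"{st}_S"], row[f"{st}_T"])
                    triple = tuple(int(c) if c != "" else None for c in cells)
                else:
                    triple = None
                tasks[(row["patient_id"], st)] = {
                    "triple": triple,
                    "triage": row[f"{st}_triage"],
                }
    return tasks


def write_queue_jsonl(queue: Iterable[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entry in queue:
            fh.write(json.dumps(entry) + "\n")


def read_queue_jsonl(path) -> list[dict]:
    entries = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                entries.append(json.loads(line))
    return entries


# --- gold labels ------------------------------------------------------------

_GOLD_FIELDS = [
    "patient_id",
    "specimen_type",
    "P",
    "S",
    "T",
    "status",
    "corruption",
    "expected_triage",
]


def write_gold_csv(gold, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GOLD_FIELDS)
        for g in gold:
            if g.triple is None:
                p = s = t = ""
                status = "not_found"
            else:
                p, s, t = g.triple
                status = "found"
            writer.writerow(
                [
                    g.patient_id,
                    g.specimen_type,
                    p,
                    s,
                    t,
                    status,
                    g.corruption,
                    g.expected_triage,
                ]
            )


def read_gold_csv(path) -> dict:
    """(patient_id, specimen) -> {'triple', 'corruption', 'expected_triage'}."""
    gold = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_GOLD_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"gold file missing column(s) {sorted(missing)}")
        for row in reader:
            triple = (
                (int(row["P"]), int(row["S"]), int(row["T"]))
                if row["status"] == "found"
                else None
            )
            gold[(row["patient_id"], row["specimen_type"])] = {
                "triple": triple,
                "corruption": row["corruption"],
                "expected_triage": row["expected_triage"],
            }
    return gold
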