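"""Group mentions into per-patient extraction tasks, triage, and aggregate.

The unit of work is the (patient, specimen_type) *task*: every patient owns
exactly two tasks, one for prostate surgery and one for prostate needle
biopsy, regardless of how many notes or mentions exist.  A task is triaged
*complicated* -- routed to a human-review work queue -- when its evidence is

* inaccurate   (a mention whose read components violate P+S=T or the ranges),
* incomplete   (only partial mentions and no valid mention supplies a score),
* conflicting  (valid mentions from different notes disagree), or
* unclassified_specimen (the only valid evidence could not be attributed to
  surgery or biopsy).

Uncomplicated tasks are resolved automatically: the final score is the
maximum valid mention by total T, with ties broken by the higher primary
pattern (clinically more aggressive) and then first-seen order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .mention_extractor import ComponentTriple, GleasonMention, Validity
from .specimen_classifier import Specimen, SpecimenClass

SPECIMEN_TYPES = ("surgery", "biopsy")
REASONS = ("inaccurate", "incomplete", "conflicting", "unclassified_specimen")


class Triage(str, Enum):
    UNCOMPLICATED = "uncomplicated"
    COMPLICATED = "complicated"


@dataclass
class ExtractionTask:
    patient_id: str
    specimen_type: str
    mentions: list = field(default_factory=list)
    triage: Optional[Triage] = None
    reasons: frozenset = frozenset()


@dataclass
class PatientGleasonRecord:
    patient_id: str
    surgery_score: Optional[ComponentTriple]
    biopsy_score: Optional[ComponentTriple]
    surgery_triage: Triage
    biopsy_triage: Triage
    surgery_reasons: tuple = ()
    biopsy_reasons: tuple = ()


def _specimen_value(mention: GleasonMention) -> Specimen:
    specimen = mention.specimen
    if specimen is None:
        return Specimen.UNCLASSIFIED
    if isinstance(specimen, SpecimenClass):
        return specimen.value
    return Specimen(specimen)


def build_tasks(
    mentions: Iterable[GleasonMention],
    patient_ids: Iterable[str] = (),
) -> list[ExtractionTask]:
    """Two tasks per patient; mentions routed by specimen class.

    ``patient_ids`` supplies the cohort roster so that patients without any
    mention still receive their two (empty) tasks.  Unclassified mentions are
    attached to both of the patient's tasks; triage decides whether they
    matter.
    """
    mentions = list(mentions)
    for m in mentions:
        if m.patient_id is None:
            raise ValueError(f"mention from note {m.note_id!r} has no patient_id")
    roster = sorted(set(patient_ids) | {m.patient_id for m in mentions})
    by_patient: dict[str, list[GleasonMention]] = {pid: [] for pid in roster}
    for m in mentions:
        by_patient[m.patient_id].append(m)
    tasks = []
    for pid in roster:
        for specimen_type in SPECIMEN_TYPES:
            routed = [
                m
                for m in by_patient[pid]
                if _specimen_value(m).value in (specimen_type, "unclassified")
            ]
            tasks.append(ExtractionTask(pid, specimen_type, routed))
    return tasks


def detect_conflicts(task: ExtractionTask, conflict_mode: str = "triples") -> bool:
    """True iff valid mentions from *different notes* carry different scores.

    ``conflict_mode`` selects what "different" means: ``"triples"`` compares
    full (P, S, T) triples (so 3+4=7 vs 4+3=7 conflicts), ``"totals"``
    compares only T.  Mentions within one note never conflict under this
    rule.
    """
    if conflict_mode not in ("triples", "totals"):
        raise ValueError(f"unknown conflict mode {conflict_mode!r}")
    pairs = {
        (
            m.triple.astuple() if conflict_mode == "triples" else m.triple.total,
            m.note_id,
        )
        for m in task.mentions
        if m.validity is Validity.VALID
    }
    return any(
        k1 != k2 and n1 != n2 for k1, n1 in pairs for k2, n2 in pairs
    )


def triage_task(
    task: ExtractionTask, conflict_mode: str = "triples"
) -> ExtractionTask:
    """Attach triage flag and complication reasons to a task (in place).

    An incomplete mention does not escalate the task when another valid
    mention already supplies a complete score (casual "Gleason 7" references
    are redundant, not complications).  A task with zero mentions is simply
    uncomplicated with outcome not_found.
    """
    reasons = set()
    valid = [m for m in task.mentions if m.validity is Validity.VALID]
    if any(m.validity is Validity.INACCURATE for m in task.mentions):
        reasons.add("inaccurate")
    if any(m.validity is Validity.INCOMPLETE for m in task.mentions) and not valid:
        reasons.add("incomplete")
    if detect_conflicts(task, conflict_mode):
        reasons.add("conflicting")
    classified_valid = [
        m for m in valid if _specimen_value(m).value == task.specimen_type
    ]
    unclassified_valid = [
        m for m in valid if _specimen_value(m) is Specimen.UNCLASSIFIED
    ]
    if unclassified_valid and not classified_valid:
        reasons.add("unclassified_specimen")
    task.reasons = frozenset(reasons)
    task.triage = Triage.COMPLICATED if reasons else Triage.UNCOMPLICATED
    return task


def aggregate_task(task: ExtractionTask) -> Optional[ComponentTriple]:
    """Maximum valid score: by total T, ties by primary P, then first-seen.

    Returns ``None`` ("not found") when the task holds no valid mention.
    Permutation-invariant up to the deterministic first-seen tie-break.
    """
    best: Optional[GleasonMention] = None
    for m in task.mentions:
        if m.validity is not Validity.VALID:
            continue
        if best is None or (m.triple.total, m.triple.primary) > (
            best.triple.total,
            best.triple.primary,
        ):
            best = m
    return best.triple if best is not None else None


def assemble_cohort(
    tasks: Iterable[ExtractionTask],
) -> tuple[list[PatientGleasonRecord], list[dict]]:
    """Split triaged tasks into automated records and a human work queue.

    Every task contributes its (draft) aggregate to the patient record;
    complicated tasks additionally emit a work-queue entry carrying the
    draft, the reasons, and the mention-level evidence for the reviewer.
    Output is stable, ordered by patient_id.
    """
    by_patient: dict[str, dict[str, ExtractionTask]] = {}
    for task in tasks:
        if task.triage is None:
            raise ValueError(
                f"task ({task.patient_id}, {task.specimen_type}) is not triaged"
            )
        by_patient.setdefault(task.patient_id, {})[task.specimen_type] = task

    records, queue = [], []
    for pid in sorted(by_patient):
        pair = by_patient[pid]
        if set(pair) != set(SPECIMEN_TYPES):
            raise ValueError(f"patient {pid} is missing a specimen task")
        scores = {st: aggregate_task(pair[st]) for st in SPECIMEN_TYPES}
        records.append(
            PatientGleasonRecord(
                patient_id=pid,
                surgery_score=scores["surgery"],
                biopsy_score=scores["biopsy"],
                surgery_triage=pair["surgery"].triage,
                biopsy_triage=pair["biopsy"].triage,
                surgery_reasons=tuple(sorted(pair["surgery"].reasons)),
                biopsy_reasons=tuple(sorted(pair["biopsy"].reasons)),
            )
        )
        for st in SPECIMEN_TYPES:
            task = pair[st]
            if task.triage is Triage.COMPLICATED:
                draft = scores[st]
                queue.append(
                    {
                        "patient_id": pid,
                        "specimen_type": st,
                        "reasons": sorted(task.reasons),
                        "draft": None if draft is None else list(draft.astuple()),
                        "mentions": [
                            {
                                "note_id": m.note_id,
                                "anchor": [m.anchor_span.start, m.anchor_span.end],
                                "evidence": (
                                    None
                                    if m.evidence_span is None
                                    else [m.evidence_span.start, m.evidence_span.end]
                                ),
                                "triple": list(m.triple.astuple()),
                                "validity": m.validity.value,
                                "specimen": _specimen_value(m).value,
                            }
                            for m in task.mentions
                        ],
                    }
                )
    return records, queue
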