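"""End-to-end extraction: notes in, patient records and work queue out."""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from .corpus_io import Note
from .lexicon import Lexicon, default_lexicon
from .patient_assembly import (
    ExtractionTask,
    PatientGleasonRecord,
    assemble_cohort,
    build_tasks,
    triage_task,
)
from .specimen_classifier import DEFAULT_SCHEDULE, WindowSchedule, extract_note

logger = logging.getLogger("gleason_nlp")


def run_extract(
    notes: Iterable[Note],
    lexicon: Optional[Lexicon] = None,
    schedule: WindowSchedule = DEFAULT_SCHEDULE,
    conflict_mode: str = "triples",
) -> tuple[list[PatientGleasonRecord], list[dict], list[ExtractionTask]]:
    """Extract -> classify -> triage -> aggregate over a whole corpus.

    Deterministic for fixed inputs.  Returns the per-patient records, the
    human-review work queue, and the triaged tasks themselves (for scoring).
    """
    notes = list(notes)
    lexicon = lexicon or default_lexicon()
    mentions = []
    for note in notes:
        note_mentions = extract_note(note, lexicon, schedule)
        for mention in note_mentions:
            mention.patient_id = note.patient_id
            logger.debug(
                "mention patient=%s note=%s anchor=[%d,%d) triple=%s "
                "validity=%s specimen=%s",
                note.patient_id,
                note.note_id,
                mention.anchor_span.start,
                mention.anchor_span.end,
                mention.triple.astuple(),
                mention.validity.value,
                mention.specimen.value.value,
            )
        mentions.extend(note_mentions)

    tasks = build_tasks(mentions, patient_ids=[n.patient_id for n in notes])
    for task in tasks:
        triage_task(task, conflict_mode)
        if task.reasons:
            logger.debug(
                "task patient=%s specimen=%s complicated reasons=%s",
                task.patient_id,
                task.specimen_type,
                sorted(task.reasons),
            )
    records, queue = assemble_cohort(tasks)
    logger.info(
        "extracted %d patients (%d tasks): %d complicated -> human queue",
        len(records),
        len(tasks),
        len(queue),
    )
    return records, queue, tasks
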