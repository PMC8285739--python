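"""Assign each Gleason mention to prostate surgery or prostate needle biopsy.

Pathology notes describe a single specimen, so they are classified once at
the note level (classifier before extractor) and the class is stamped onto
every mention.  Clinical notes can cite scores from several specimens, so the
extractor runs first and each mention is classified from its own context:
surgery/biopsy cues are collected in a window centered on the mention, the
best (lowest) tier wins, ties within a tier break by character proximity, and
the window widens through a schedule until a cue is found or the whole note
is exhausted.  An exact tie between a surgery and a biopsy cue at the same
tier and distance is left unclassified rather than guessed, so triage can
escalate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .lexicon import Lexicon, Span, TermMatch, default_lexicon, match_terms
from .mention_extractor import GleasonMention, extract_mentions


class Specimen(str, Enum):
    SURGERY = "surgery"
    BIOPSY = "biopsy"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SpecimenClass:
    value: Specimen
    evidence_tier: Optional[int] = None
    evidence_span: Optional[Span] = None


UNCLASSIFIED = SpecimenClass(Specimen.UNCLASSIFIED)


@dataclass(frozen=True)
class WindowSchedule:
    """Ordered, strictly increasing search radii; ``None`` = the whole note."""

    radii: tuple

    def __post_init__(self) -> None:
        radii = tuple(self.radii)
        if not radii:
            raise ValueError("window schedule must be non-empty")
        finite = [r for r in radii if r is not None]
        if any(not isinstance(r, int) or r <= 0 for r in finite):
            raise ValueError("window radii must be positive integers")
        if any(a >= b for a, b in zip(finite, finite[1:])):
            raise ValueError("window radii must be strictly increasing")
        if None in radii and radii.index(None) != len(radii) - 1:
            raise ValueError("the whole-note window must come last")
        if radii[-1] is not None:
            radii = radii + (None,)  # always end on the whole note
        object.__setattr__(self, "radii", radii)


DEFAULT_SCHEDULE = WindowSchedule((150, 500, None))

_CUE_CATEGORIES = (("surgery_cue", Specimen.SURGERY), ("biopsy_cue", Specimen.BIOPSY))


def _cues_in(text: str, lexicon: Lexicon) -> list[tuple[TermMatch, Specimen]]:
    cues = []
    for category, specimen in _CUE_CATEGORIES:
        cues.extend((m, specimen) for m in match_terms(text, category, lexicon))
    return cues


def _best_cue(
    cues: list[tuple[TermMatch, Specimen]], reference: float
) -> SpecimenClass:
    best_tier = min(m.tier for m, _ in cues)
    contenders = [(m, sp) for m, sp in cues if m.tier == best_tier]
    best_dist = min(abs(m.span.midpoint - reference) for m, _ in contenders)
    nearest = [
        (m, sp)
        for m, sp in contenders
        if math.isclose(abs(m.span.midpoint - reference), best_dist)
    ]
    if len({sp for _, sp in nearest}) > 1:
        # dead heat between opposing cues: refuse to guess
        return UNCLASSIFIED
    match, specimen = nearest[0]
    return SpecimenClass(specimen, evidence_tier=match.tier, evidence_span=match.span)


def classify_mention_context(
    text: str,
    mention_span: Span,
    lexicon: Lexicon | None = None,
    schedule: WindowSchedule = DEFAULT_SCHEDULE,
) -> SpecimenClass:
    """Classify one clinical-note mention from its surrounding context.

    For each radius in the schedule, cues within the window around the
    mention midpoint are collected; the first non-empty window decides
    (best tier, then proximity) and later windows can never override it.
    """
    lexicon = lexicon or default_lexicon()
    mid = mention_span.midpoint
    for radius in schedule.radii:
        if radius is None:
            lo, hi = 0, len(text)
        else:
            lo = max(0, int(mid) - radius)
            hi = min(len(text), int(mid) + radius)
        cues = [
            (TermMatch(Span(m.span.start + lo, m.span.end + lo), m.term, m.tier), sp)
            for m, sp in _cues_in(text[lo:hi], lexicon)
        ]
        if cues:
            return _best_cue(cues, mid)
    return UNCLASSIFIED


def classify_pathology_note(
    text: str,
    lexicon: Lexicon | None = None,
    schedule: WindowSchedule | None = None,
) -> SpecimenClass:
    """Single note-level specimen class for a pathology note.

    A pathology report describes one specimen, so cues anywhere in the text
    are pooled; the best tier wins and, within it, the earliest occurrence
    (pathology headers lead the report).  The result is stamped on every
    mention later extracted from the note.
    """
    lexicon = lexicon or default_lexicon()
    cues = _cues_in(text, lexicon)
    if not cues:
        return UNCLASSIFIED
    best_tier = min(m.tier for m, _ in cues)
    match, specimen = min(
        ((m, sp) for m, sp in cues if m.tier == best_tier),
        key=lambda pair: pair[0].span.start,
    )
    return SpecimenClass(specimen, evidence_tier=match.tier, evidence_span=match.span)


def extract_note(
    note,
    lexicon: Lexicon | None = None,
    schedule: WindowSchedule = DEFAULT_SCHEDULE,
) -> list[GleasonMention]:
    """Run the note-type-appropriate module ordering and classify mentions.

    Pathology: classifier first, then extractor (one class per note).
    Clinical: extractor first, then per-mention contextual classification.
    """
    lexicon = lexicon or default_lexicon()
    if note.note_type == "pathology":
        note_class = classify_pathology_note(note.text, lexicon)
        mentions = extract_mentions(note, lexicon)
        for mention in mentions:
            mention.specimen = note_class
        return mentions
    if note.note_type == "clinical":
        mentions = extract_mentions(note, lexicon)
        for mention in mentions:
            mention.specimen = classify_mention_context(
                note.text, mention.anchor_span, lexicon, schedule
            )
        return mentions
    raise ValueError(
        f"unknown note_type {note.note_type!r} for note {note.note_id!r}; "
        "expected 'clinical' or 'pathology'"
    )
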