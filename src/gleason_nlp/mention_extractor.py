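"""Detect Gleason-score mentions and parse their (P, S, T) components.

A fully specified Gleason score has a primary pattern P (3-5, the most
prevalent histologic grade), a secondary pattern S (3-5, the second most
prevalent), and a total T = P + S (6-10).  Notes render scores in several
surface grammars; anchored on a lexicon hit ("Gleason", "GS"), a bounded
window of surrounding text is scanned for, in order of precedence:

(a) ``P+S=T``            e.g. "Gleason 3+4=7"
(c) ``T (P+S)``          e.g. "GS 7 (4+3)"
(b) ``P+S``              e.g. "Gleason 4+3"
(q) labeled component    e.g. "Primary GS was 4" (qualifier before the anchor)
(d) lone total ``T``     e.g. "Gleason 9", only accepted for T in 6-10

Digits are always read verbatim and never clamped into range: a note stating
"Gleason 3+4=8" yields the triple (3, 4, 8) which validation then flags as
*inaccurate*.  When exactly two of the three components are read, the third is
derived through P+S=T and marked as derived; a lone total is deliberately left
incomplete rather than split into a guessed (P, S).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .lexicon import Lexicon, Span, default_lexicon, match_terms

PRIMARY_RANGE = range(3, 6)
SECONDARY_RANGE = range(3, 6)
TOTAL_RANGE = range(6, 11)

#: component search window after / before the anchor, in characters
DEFAULT_WINDOW_AFTER = 60
DEFAULT_WINDOW_BEFORE = 30


class Validity(str, Enum):
    VALID = "valid"
    INACCURATE = "inaccurate"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class ComponentTriple:
    """(P, S, T) with bookkeeping of which field was derived via P+S=T."""

    primary: Optional[int] = None
    secondary: Optional[int] = None
    total: Optional[int] = None
    derived: frozenset = frozenset()

    def astuple(self) -> tuple:
        return (self.primary, self.secondary, self.total)

    @property
    def n_present(self) -> int:
        return sum(v is not None for v in self.astuple())

    @property
    def is_complete(self) -> bool:
        return self.n_present == 3


@dataclass
class GleasonMention:
    """One detected score occurrence inside a note."""

    triple: ComponentTriple
    anchor_span: Span
    evidence_span: Optional[Span]
    validity: Validity
    note_id: Optional[str] = None
    note_type: Optional[str] = None
    patient_id: Optional[str] = None
    specimen: object = None  # SpecimenClass, stamped by the classifier


def find_mentions(text: str, lexicon: Lexicon | None = None) -> list[Span]:
    """Anchor spans of all Gleason mentions, ordered by offset."""
    lexicon = lexicon or default_lexicon()
    return [m.span for m in match_terms(text, "gleason_anchor", lexicon)]


def complete_components(triple: ComponentTriple) -> ComponentTriple:
    """Fill exactly one missing component via P+S=T; otherwise return as-is.

    Never overwrites a value that was read from the text; idempotent.
    """
    if triple.n_present != 2:
        return triple
    p, s, t = triple.astuple()
    if t is None:
        return replace(triple, total=p + s, derived=triple.derived | {"total"})
    if s is None:
        return replace(triple, secondary=t - p, derived=triple.derived | {"secondary"})
    return replace(triple, primary=t - s, derived=triple.derived | {"primary"})


def validate_triple(triple: ComponentTriple) -> Validity:
    """Classify a (completed) triple as valid, inaccurate, or incomplete.

    Incomplete: any component still absent.  Inaccurate: any component out of
    range (P, S in 3-5; T in 6-10) or, for a fully read triple, P+S != T.
    Out-of-range triples are carried as-is, never silently repaired.
    """
    p, s, t = triple.astuple()
    if triple.n_present < 3:
        return Validity.INCOMPLETE
    if p not in PRIMARY_RANGE or s not in SECONDARY_RANGE or t not in TOTAL_RANGE:
        return Validity.INACCURATE
    if p + s != t:
        return Validity.INACCURATE
    return Validity.VALID


# --- surface grammars -------------------------------------------------------

_SENTENCE_BOUNDARY = re.compile(r"\.\s")
_RE_A = re.compile(r"(\d)\s*\+\s*(\d)\s*=\s*(\d{1,2})")
_RE_C = re.compile(r"(\d{1,2})\s*\(\s*(\d)\s*\+\s*(\d)\s*\)")
_RE_B = re.compile(r"(\d)\s*\+\s*(\d)(?!\s*=)")
# lone total: 6-10, not part of a sum/fraction/range/percentage/decimal
_RE_D = re.compile(r"(?<![-\d+=./])\b(10|[6-9])\b(?![-\d/%])")
_RE_QUALIFIER = re.compile(r"\b(primary|secondary|total)\b\W{0,12}$", re.IGNORECASE)
_RE_LONE_NUMBER = re.compile(r"\b(\d{1,2})\b")


def _after_segment(text, anchor: Span, width: int, stop: int | None):
    end = min(len(text), anchor.end + width)
    if stop is not None:
        end = min(end, stop)
    seg = text[anchor.end : end]
    m = _SENTENCE_BOUNDARY.search(seg)
    if m:
        seg = seg[: m.start()]
    return seg, anchor.end


def _before_segment(text, anchor: Span, width: int, stop: int | None):
    start = max(0, anchor.start - width)
    if stop is not None:
        start = max(start, stop)
    seg = text[start : anchor.start]
    last = None
    for m in _SENTENCE_BOUNDARY.finditer(seg):
        last = m
    if last:
        start += last.end()
        seg = seg[last.end() :]
    return seg, start


def _parse_with_span(
    text: str,
    anchor: Span,
    *,
    window_after: int = DEFAULT_WINDOW_AFTER,
    window_before: int = DEFAULT_WINDOW_BEFORE,
    stop_after: int | None = None,
    stop_before: int | None = None,
) -> tuple[ComponentTriple, Optional[Span]]:
    after = _after_segment(text, anchor, window_after, stop_after)
    before = _before_segment(text, anchor, window_before, stop_before)

    for seg, offset in (after, before):
        m = _RE_A.search(seg)
        if m:
            p, s, t = (int(g) for g in m.groups())
            return (
                ComponentTriple(p, s, t),
                Span(offset + m.start(), offset + m.end()),
            )
        m = _RE_C.search(seg)
        if m:
            t, p, s = (int(g) for g in m.groups())
            return (
                ComponentTriple(p, s, t),
                Span(offset + m.start(), offset + m.end()),
            )
        m = _RE_B.search(seg)
        if m:
            p, s = (int(g) for g in m.groups())
            return (
                ComponentTriple(p, s, None),
                Span(offset + m.start(), offset + m.end()),
            )

    qual = _RE_QUALIFIER.search(text[max(0, anchor.start - 24) : anchor.start])
    if qual:
        seg, offset = after
        m = _RE_LONE_NUMBER.search(seg)
        if m:
            value = int(m.group(1))
            span = Span(offset + m.start(), offset + m.end())
            which = qual.group(1).lower()
            if which == "primary":
                return ComponentTriple(primary=value), span
            if which == "secondary":
                return ComponentTriple(secondary=value), span
            return ComponentTriple(total=value), span

    for seg, offset in (after, before):
        m = _RE_D.search(seg)
        if m:
            return (
                ComponentTriple(total=int(m.group(1))),
                Span(offset + m.start(), offset + m.end()),
            )

    return ComponentTriple(), None


def parse_components(
    text: str,
    anchor: Span,
    *,
    window_after: int = DEFAULT_WINDOW_AFTER,
    window_before: int = DEFAULT_WINDOW_BEFORE,
) -> ComponentTriple:
    """Parse the (possibly partial) component triple around one anchor.

    The window after the anchor is scanned first, then the window before;
    both stop at a sentence boundary (period + whitespace).  Returns a fully
    absent triple when no digits are recoverable.
    """
    triple, _ = _parse_with_span(
        text, anchor, window_after=window_after, window_before=window_before
    )
    return triple


def extract_mentions(
    note,
    lexicon: Lexicon | None = None,
    *,
    window_after: int = DEFAULT_WINDOW_AFTER,
    window_before: int = DEFAULT_WINDOW_BEFORE,
) -> list[GleasonMention]:
    """Full per-note extraction: anchors -> parse -> complete -> validate.

    ``note`` may be a corpus record (with ``text``/``note_id``/``note_type``
    attributes) or a plain string.  Component search for one anchor never
    crosses into the territory of a neighboring anchor, so multiple mentions
    in one note stay independent.
    """
    if isinstance(note, str):
        text, note_id, note_type = note, None, None
    else:
        text, note_id, note_type = note.text, note.note_id, note.note_type
    lexicon = lexicon or default_lexicon()
    anchors = find_mentions(text, lexicon)
    mentions = []
    for i, anchor in enumerate(anchors):
        stop_after = anchors[i + 1].start if i + 1 < len(anchors) else None
        stop_before = anchors[i - 1].end if i > 0 else None
        raw, evidence = _parse_with_span(
            text,
            anchor,
            window_after=window_after,
            window_before=window_before,
            stop_after=stop_after,
            stop_before=stop_before,
        )
        triple = complete_components(raw)
        mentions.append(
            GleasonMention(
                triple=triple,
                anchor_span=anchor,
                evidence_span=evidence,
                validity=validate_triple(triple),
                note_id=note_id,
                note_type=note_type,
            )
        )
    return mentions
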