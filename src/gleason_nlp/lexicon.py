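"""Configurable term lists driving mention detection and specimen classification.

A :class:`Lexicon` holds three categories of surface terms:

* ``gleason_anchor`` -- words that announce a Gleason score ("Gleason", "GS");
* ``surgery_cue``    -- evidence that a score came from a prostatectomy
  specimen ("RRP", "radical prostatectomy", ...);
* ``biopsy_cue``     -- evidence for a prostate needle biopsy ("PNBx",
  "core biopsy", ...).

Cue terms carry a *tier*: tier 1 marks the most specific, highest-priority
terms; larger tiers are progressively weaker evidence.  The bundled default
lexicon is a reconstruction built from the clinically standard vocabulary; any
entry can be overridden through the YAML/JSON config interface.

Matching is case-insensitive and whole-token: a term never matches inside a
longer alphanumeric run, so "GS" does not fire inside "drugs".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

import yaml

CATEGORIES = ("gleason_anchor", "surgery_cue", "biopsy_cue")

# A token boundary for clinical text: letters and digits glue, everything else
# (whitespace, punctuation, "/") separates.
_BOUND_L = r"(?<![0-9A-Za-z])"
_BOUND_R = r"(?![0-9A-Za-z])"


class LexiconError(ValueError):
    """Raised for malformed lexicon configuration."""


@dataclass(frozen=True, order=True)
class Span:
    """0-based half-open character interval of the raw note text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def slice(self, text: str) -> str:
        return text[self.start : self.end]

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class LexiconTerm:
    """One surface form with its category and priority tier (1 = strongest)."""

    surface: str
    category: str
    tier: int = 2

    def __post_init__(self) -> None:
        if not self.surface or not self.surface.strip():
            raise LexiconError("lexicon term surface must be non-empty")
        if self.category not in CATEGORIES:
            raise LexiconError(
                f"unknown lexicon category {self.category!r} for surface "
                f"{self.surface!r}; expected one of {CATEGORIES}"
            )
        if not isinstance(self.tier, int) or self.tier < 1:
            raise LexiconError(
                f"tier must be a positive integer, got {self.tier!r} "
                f"for surface {self.surface!r}"
            )


class TermMatch(NamedTuple):
    span: Span
    term: LexiconTerm
    tier: int


@dataclass(frozen=True)
class Lexicon:
    terms: tuple[LexiconTerm, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for term in self.terms:
            key = (term.surface.casefold(), term.category)
            if key in seen:
                raise LexiconError(
                    f"duplicate lexicon entry {term.surface!r} in category "
                    f"{term.category!r}"
                )
            seen.add(key)
        for category in CATEGORIES:
            if not any(t.category == category for t in self.terms):
                raise LexiconError(f"lexicon has no {category} term")

    def terms_in(self, category: str) -> tuple[LexiconTerm, ...]:
        if category not in CATEGORIES:
            raise LexiconError(f"unknown lexicon category {category!r}")
        return tuple(t for t in self.terms if t.category == category)


def load_lexicon(source: Mapping | str | bytes) -> Lexicon:
    """Build a validated :class:`Lexicon` from parsed or raw YAML/JSON config.

    The schema is a mapping with an optional ``version`` string and a ``terms``
    list of ``{surface, category[, tier]}`` entries; ``tier`` defaults to 2.
    Unknown categories and malformed entries raise :class:`LexiconError`
    naming the offending entry.  Extra top-level keys (e.g. ``windows``) are
    ignored so one config file can also carry classifier settings.
    """
    if isinstance(source, (str, bytes)):
        try:
            source = yaml.safe_load(source)
        except yaml.YAMLError as exc:  # pragma: no cover - yaml detail
            raise LexiconError(f"config does not parse as YAML/JSON: {exc}") from exc
    if not isinstance(source, Mapping):
        raise LexiconError("lexicon config must be a mapping")
    raw_terms = source.get("terms")
    if not isinstance(raw_terms, Iterable) or isinstance(raw_terms, (str, bytes)):
        raise LexiconError("lexicon config must contain a 'terms' list")
    terms = []
    for i, entry in enumerate(raw_terms):
        if not isinstance(entry, Mapping):
            raise LexiconError(f"term #{i} is not a mapping: {entry!r}")
        unknown = set(entry) - {"surface", "category", "tier"}
        if unknown:
            raise LexiconError(f"term #{i} has unknown keys {sorted(unknown)}")
        try:
            terms.append(
                LexiconTerm(
                    surface=entry.get("surface", ""),
                    category=entry.get("category", ""),
                    tier=entry.get("tier", 2),
                )
            )
        except LexiconError as exc:
            raise LexiconError(f"term #{i}: {exc}") from exc
    version = str(source.get("version", "unversioned"))
    return Lexicon(terms=tuple(terms), version=version)


def load_lexicon_file(path) -> Lexicon:
    with open(path, "r", encoding="utf-8") as fh:
        return load_lexicon(fh.read())


@lru_cache(maxsize=1)
def _default_config_text() -> str:
    return (
        resources.files("gleason_nlp.data")
        .joinpath("default_lexicon.yaml")
        .read_text(encoding="utf-8")
    )


def default_config() -> dict:
    """Parsed content of the bundled default configuration file."""
    return yaml.safe_load(_default_config_text())


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    """The bundled expert lexicon; deterministic and versioned."""
    return load_lexicon(default_config())


@lru_cache(maxsize=128)
def _category_pattern(lexicon: Lexicon, category: str) -> re.Pattern:
    # Longest-first alternation => at any offset the longest surface wins,
    # and finditer yields non-overlapping leftmost matches.
    surfaces = sorted(
        {t.surface for t in lexicon.terms_in(category)}, key=len, reverse=True
    )
    alternation = "|".join(re.escape(s) for s in surfaces)
    return re.compile(_BOUND_L + "(?:" + alternation + ")" + _BOUND_R, re.IGNORECASE)


def match_terms(text: str, category: str, lexicon: Lexicon) -> list[TermMatch]:
    """All non-overlapping, case-insensitive, whole-token term occurrences.

    Returned in order of start offset; each span sliced from ``text`` and
    case-folded equals a lexicon surface.  Overlaps are resolved greedily
    left-to-right, preferring the longest surface at each position.
    """
    if category not in CATEGORIES:
        raise LexiconError(f"unknown lexicon category {category!r}")
    if not text:
        return []
    pattern = _category_pattern(lexicon, category)
    by_surface = {t.surface.casefold(): t for t in lexicon.terms_in(category)}
    matches = []
    for m in pattern.finditer(text):
        term = by_surface[m.group(0).casefold()]
        matches.append(TermMatch(Span(m.start(), m.end()), term, term.tier))
    return matches
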