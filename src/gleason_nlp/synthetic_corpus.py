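"""Synthetic clinical/pathology note corpora with per-task gold labels.

Real prostate-cancer chart text cannot ship with the package, so the
generator emulates its load-bearing features: per patient, a biopsy Gleason
score (and, for surgical patients, a prostatectomy score at least as high --
pathologic upgrading), rendered into pathology reports and a stream of
clinical notes in varied surface grammars ("3+4=7", "7 (4+3)", "4+3", lone
totals) with specimen cues, plus score-free distractor notes.  Controlled
corruptions are injected per (patient, specimen) task:

* ``inaccurate_sum``       -- a rendered total violating P+S=T,
* ``missing_component``    -- only a primary pattern recoverable anywhere,
* ``cross_note_conflict``  -- a second note asserting a different valid score.

Every corrupted task's gold label expects triage *complicated*; clean tasks
expect *uncomplicated*.  Generation is fully deterministic under the
mandatory seed, with per-patient substreams so one patient's draw never
cascades into another's.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import yaml

from .corpus_io import Note

CORRUPTIONS = ("inaccurate_sum", "missing_component", "cross_note_conflict")
_GRADES = (3, 4, 5)

_BANK_KEYS = (
    "cues_biopsy",
    "cues_surgery",
    "clinical_complete",
    "clinical_total_only",
    "clinical_combined",
    "clinical_distractor",
    "pathology_biopsy",
    "pathology_surgery",
    "pathology_distractor",
    "conflict_clinical",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GoldLabel:
    """Ground truth for one (patient, specimen_type) extraction task."""

    patient_id: str
    specimen_type: str
    triple: Optional[tuple]  # (P, S, T) or None for not_found
    corruption: str = "none"
    expected_triage: str = "uncomplicated"


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for corpus generation.

    Defaults reflect the cohort the tool is meant for: ~18.2 clinical and
    ~3.6 pathology notes per patient, a 4.85% task complication rate split
    evenly across corruption kinds, and surgery performed for ~56% of
    patients.  Grade mixes are Dirichlet-sampled, with the biopsy
    distribution skewed lower than the surgery distribution.
    """

    n_patients: int
    seed: int
    complication_rate: float = 0.0485
    corruption_split: tuple = (1 / 3, 1 / 3, 1 / 3)
    clinical_notes_mean: float = 18.2
    pathology_notes_mean: float = 3.6
    p_surgery: float = 0.56
    p_upgrade: float = 0.9
    grade_alpha_biopsy: tuple = (5.0, 3.0, 0.8)
    grade_alpha_surgery: tuple = (2.0, 4.0, 1.6)
    template_bank: Optional[Mapping] = None

    def __post_init__(self) -> None:
        if not isinstance(self.n_patients, int) or self.n_patients < 1:
            raise ConfigurationError("n_patients must be a positive integer")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError("an explicit non-negative seed is required")
        if not 0.0 <= self.complication_rate <= 1.0:
            raise ConfigurationError("complication_rate must be in [0, 1]")
        split = tuple(float(x) for x in self.corruption_split)
        if len(split) != len(CORRUPTIONS) or any(x < 0 for x in split):
            raise ConfigurationError("corruption_split needs 3 non-negative weights")
        if abs(sum(split) - 1.0) > 1e-9:
            raise ConfigurationError("corruption_split must sum to 1")
        for name in ("p_surgery", "p_upgrade"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@lru_cache(maxsize=1)
def _default_bank() -> dict:
    text = (
        resources.files("gleason_nlp.data")
        .joinpath("templates.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def _bank(params_bank: Optional[Mapping]) -> Mapping:
    bank = params_bank if params_bank is not None else _default_bank()
    for key in _BANK_KEYS:
        if not bank.get(key):
            raise ConfigurationError(f"template bank entry {key!r} is empty/missing")
    return bank


def assign_patterns_from_composition(composition: Mapping) -> tuple[int, int]:
    """Primary/secondary patterns from a grade composition of a specimen.

    The primary pattern is the most prevalent grade, the secondary the
    second most prevalent; a single-grade specimen has S = P, and an exact
    tie in prevalence is awarded to the higher (more aggressive) grade.
    """
    if not composition:
        raise ValueError("composition must be non-empty")
    items = []
    for grade, fraction in composition.items():
        if grade not in _GRADES:
            raise ValueError(f"invalid grade {grade!r}; expected one of {_GRADES}")
        fraction = float(fraction)
        if fraction <= 0:
            raise ValueError(f"fraction for grade {grade} must be positive")
        items.append((grade, fraction))
    if abs(sum(f for _, f in items) - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    ranked = sorted(items, key=lambda gf: (-gf[1], -gf[0]))
    primary = ranked[0][0]
    secondary = ranked[1][0] if len(ranked) > 1 else primary
    return primary, secondary


def _sample_triple(rng: np.random.Generator, alpha) -> tuple[int, int, int]:
    fractions = rng.dirichlet(alpha)
    composition = dict(zip(_GRADES, fractions))
    p, s = assign_patterns_from_composition(composition)
    return (p, s, p + s)


_RE_SUM_TOTAL = re.compile(r"\d\s*\+\s*\d\s*=\s*(\d{1,2})")
_RE_PAREN_TOTAL = re.compile(r"(\d{1,2})\s*\(\s*\d\s*\+\s*\d\s*\)")
_RE_SCORE_EXPR = re.compile(
    r"(?:Gleason(?:\s+score)?|GS)\s*"
    r"(?:\d{1,2}\s*\(\s*\d\s*\+\s*\d\s*\)|\d\s*\+\s*\d(?:\s*=\s*\d{1,2})?)",
    re.IGNORECASE,
)


def _perturb_total(text: str) -> str:
    """Shift the rendered total by +/-1 so that P+S != T."""
    m = _RE_SUM_TOTAL.search(text) or _RE_PAREN_TOTAL.search(text)
    if m is None:
        raise ValueError("note carries no perturbable total")
    t = int(m.group(1))
    t_new = t + 1 if t < 10 else t - 1
    return text[: m.start(1)] + str(t_new) + text[m.end(1) :]


def inject_complication(
    note: Note,
    gold: GoldLabel,
    kind: str,
    rng: np.random.Generator,
    bank: Optional[Mapping] = None,
) -> tuple[Note, GoldLabel]:
    """Apply one corruption kind to a rendered note; gold flips to complicated.

    ``inaccurate_sum`` and ``missing_component`` return a rewritten copy of
    the note; ``cross_note_conflict`` returns an *additional* clinical note
    asserting a different valid triple, to be kept alongside the original.
    """
    if kind not in CORRUPTIONS:
        raise ValueError(f"unknown corruption kind {kind!r}")
    bank = _bank(bank)
    new_gold = replace(gold, corruption=kind, expected_triage="complicated")
    if kind == "inaccurate_sum":
        return replace(note, text=_perturb_total(note.text)), new_gold
    if kind == "missing_component":
        p = gold.triple[0]
        text, n = _RE_SCORE_EXPR.subn(f"primary Gleason pattern {p}", note.text)
        if n == 0:
            raise ValueError("note carries no rewritable score expression")
        return replace(note, text=text), new_gold
    # cross_note_conflict
    p0, s0, _ = gold.triple
    pairs = [
        (p, s) for p in _GRADES for s in _GRADES if (p, s) != (p0, s0)
    ]
    p2, s2 = pairs[int(rng.integers(len(pairs)))]
    cues = bank["cues_surgery" if gold.specimen_type == "surgery" else "cues_biopsy"]
    template = bank["conflict_clinical"][
        int(rng.integers(len(bank["conflict_clinical"])))
    ]
    text = template.format(
        date=note.note_date or "2018-01-01",
        cue=cues[int(rng.integers(len(cues)))],
        p=p2,
        s=s2,
        t=p2 + s2,
    )
    conflict_note = Note(
        patient_id=note.patient_id,
        note_id=f"{note.note_id}-x",
        note_type="clinical",
        text=text,
        note_date=note.note_date,
    )
    return conflict_note, new_gold


def _pick(rng: np.random.Generator, items) -> str:
    return items[int(rng.integers(len(items)))]


def _date(rng: np.random.Generator, year: int) -> str:
    return f"{year}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"


def _sample_corruption(rng: np.random.Generator, params: GeneratorParams):
    if rng.random() >= params.complication_rate:
        return None
    split = np.asarray(params.corruption_split, dtype=float)
    return CORRUPTIONS[int(rng.choice(len(CORRUPTIONS), p=split))]


def _render_score_note(rng, bank, templates_key, cues, triple, date) -> str:
    template = _pick(rng, bank[templates_key])
    p, s, t = triple
    return template.format(p=p, s=s, t=t, cue=_pick(rng, cues), date=date)


def generate_corpus(params: GeneratorParams) -> tuple[list[Note], list[GoldLabel]]:
    """Render a reproducible corpus and its gold labels.

    Per patient: sampled biopsy score (always) and surgery score (with
    probability ``p_surgery``, upgraded to >= the biopsy total with
    probability ``p_upgrade``); pathology reports for each specimen; 1+
    clinical notes restating each score in mixed grammars; distractors up to
    the per-patient note counts; corruptions injected at
    ``complication_rate`` per scored task.
    """
    bank = _bank(params.template_bank)
    notes: list[Note] = []
    gold: list[GoldLabel] = []

    for i in range(params.n_patients):
        rng = np.random.default_rng([params.seed, i])
        pid = f"P{i:05d}"

        b_triple = _sample_triple(rng, params.grade_alpha_biopsy)
        has_surgery = rng.random() < params.p_surgery
        s_triple = None
        if has_surgery:
            s_triple = _sample_triple(rng, params.grade_alpha_surgery)
            if s_triple[2] < b_triple[2] and rng.random() < params.p_upgrade:
                for _ in range(50):
                    candidate = _sample_triple(rng, params.grade_alpha_surgery)
                    if candidate[2] >= b_triple[2]:
                        s_triple = candidate
                        break
                else:
                    s_triple = b_triple

        corruption = {"biopsy": _sample_corruption(rng, params)}
        corruption["surgery"] = (
            _sample_corruption(rng, params) if has_surgery else None
        )

        year = 2008 + int(rng.integers(0, 10))
        b_date = _date(rng, year)
        s_date = _date(rng, year + 1)

        # (task, Note) plans; task is None for distractors
        planned: list[tuple[Optional[str], str, str]] = []  # (task, type, text)
        planned.append(
            (
                "biopsy",
                "pathology",
                _render_score_note(
                    rng, bank, "pathology_biopsy", bank["cues_biopsy"], b_triple, b_date
                ),
            )
        )
        if has_surgery:
            planned.append(
                (
                    "surgery",
                    "pathology",
                    _render_score_note(
                        rng,
                        bank,
                        "pathology_surgery",
                        bank["cues_surgery"],
                        s_triple,
                        s_date,
                    ),
                )
            )
        n_path = max(len(planned), int(rng.poisson(params.pathology_notes_mean)))
        for _ in range(n_path - len(planned)):
            planned.append(
                (None, "pathology", _pick(rng, bank["pathology_distractor"]))
            )

        n_clinical = max(1, int(rng.poisson(params.clinical_notes_mean)))
        used = 0
        use_combined = (
            has_surgery
            and corruption["biopsy"] != "missing_component"
            and corruption["surgery"] != "missing_component"
            and rng.random() < 0.3
        )
        k_biopsy = 0 if corruption["biopsy"] == "missing_component" else 1 + int(
            rng.integers(0, 2)
        )
        k_surgery = (
            0
            if (not has_surgery or corruption["surgery"] == "missing_component")
            else 1 + int(rng.integers(0, 2))
        )
        if use_combined:
            k_biopsy = max(0, k_biopsy - 1)
            k_surgery = max(0, k_surgery - 1)
            template = _pick(rng, bank["clinical_combined"])
            planned.append(
                (
                    None,  # encodes both tasks; never the corruption carrier
                    "clinical",
                    template.format(
                        bcue=_pick(rng, bank["cues_biopsy"]),
                        scue=_pick(rng, bank["cues_surgery"]),
                        date=b_date,
                        bp=b_triple[0],
                        bs=b_triple[1],
                        bt=b_triple[2],
                        sp=s_triple[0],
                        ss=s_triple[1],
                        st=s_triple[2],
                    ),
                )
            )
            used += 1
        for _ in range(k_biopsy):
            planned.append(
                (
                    "biopsy",
                    "clinical",
                    _render_score_note(
                        rng, bank, "clinical_complete", bank["cues_biopsy"], b_triple, b_date
                    ),
                )
            )
            used += 1
        for _ in range(k_surgery):
            planned.append(
                (
                    "surgery",
                    "clinical",
                    _render_score_note(
                        rng, bank, "clinical_complete", bank["cues_surgery"], s_triple, s_date
                    ),
                )
            )
            used += 1
        for task, triple, date, cues in (
            ("biopsy", b_triple, b_date, bank["cues_biopsy"]),
            ("surgery", s_triple, s_date, bank["cues_surgery"]),
        ):
            if triple is None or corruption.get(task) == "missing_component":
                continue
            if rng.random() < 0.25:
                planned.append(
                    (
                        None,  # redundant lone-total restatement
                        "clinical",
                        _render_score_note(
                            rng, bank, "clinical_total_only", cues, triple, date
                        ),
                    )
                )
                used += 1
        for _ in range(max(0, n_clinical - used)):
            planned.append(
                (None, "clinical", _pick(rng, bank["clinical_distractor"]))
            )

        patient_notes = [
            Note(
                patient_id=pid,
                note_id=f"{pid}-N{j:02d}",
                note_type=note_type,
                text=text,
                note_date=b_date if task != "surgery" else s_date,
            )
            for j, (task, note_type, text) in enumerate(planned)
        ]

        patient_gold = {
            "biopsy": GoldLabel(pid, "biopsy", b_triple),
            "surgery": GoldLabel(pid, "surgery", s_triple),
        }
        extra_notes: list[Note] = []
        for task_name, kind in corruption.items():
            if kind is None:
                continue
            # the pathology report always carries a perturbable/rewritable form
            idx = next(
                j
                for j, (task, note_type, _) in enumerate(planned)
                if task == task_name and note_type == "pathology"
            )
            new_note, new_gold = inject_complication(
                patient_notes[idx], patient_gold[task_name], kind, rng, bank
            )
            patient_gold[task_name] = new_gold
            if kind == "cross_note_conflict":
                extra_notes.append(new_note)
            else:
                patient_notes[idx] = new_note

        notes.extend(patient_notes)
        notes.extend(extra_notes)
        gold.append(patient_gold["biopsy"])
        gold.append(patient_gold["surgery"])

    return notes, gold
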