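"""Synthetic corpus generation: determinism, gold fidelity, corruptions."""

import numpy as np
import pytest

from gleason_nlp.corpus_io import Note
from gleason_nlp.mention_extractor import Validity
from gleason_nlp.patient_assembly import Triage
from gleason_nlp.pipeline import run_extract
from gleason_nlp.specimen_classifier import extract_note
from gleason_nlp.synthetic_corpus import (
    CORRUPTIONS,
    ConfigurationError,
    GeneratorParams,
    GoldLabel,
    assign_patterns_from_composition,
    generate_corpus,
    inject_complication,
)

REASON_OF = {
    "inaccurate_sum": "inaccurate",
    "missing_component": "incomplete",
    "cross_note_conflict": "conflicting",
}


class TestAssignPatterns:
    @pytest.mark.parametrize(
        "composition, expected",
        [
            ({3: 0.15, 4: 0.55, 5: 0.30}, (4, 5)),
            ({3: 1.0}, (3, 3)),
            # exact tie: the higher grade takes the contested primary slot
            ({3: 0.5, 4: 0.5}, (4, 3)),
            ({3: 0.2, 4: 0.4, 5: 0.4}, (5, 4)),
        ],
    )
    def test_examples(self, composition, expected):
        assert assign_patterns_from_composition(composition) == expected

    @pytest.mark.parametrize(
        "composition",
        [
            {2: 0.5, 3: 0.5},  # invalid grade
            {3: 0.4, 4: 0.4},  # fractions do not sum to 1
            {3: -0.5, 4: 1.5},  # negative fraction
            {},
        ],
    )
    def test_invalid_inputs_rejected(self, composition):
        with pytest.raises(ValueError):
            assign_patterns_from_composition(composition)

    def test_grid_enumeration_against_sort_oracle(self):
        """All positive compositions over {3,4,5} on a 5% grid agree with
        sorting grades by (fraction, grade) descending."""
        checked = 0
        for a in range(1, 19):
            for b in range(1, 19 - a):
                c = 20 - a - b
                if c < 1:
                    continue
                comp = {3: a / 20, 4: b / 20, 5: c / 20}
                ranked = sorted(comp, key=lambda g: (-comp[g], -g))
                assert assign_patterns_from_composition(comp) == (ranked[0], ranked[1])
                checked += 1
        assert checked > 100


class TestGeneratorParams:
    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            GeneratorParams(n_patients=5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0, "seed": 1},
            {"n_patients": 2, "seed": -1},
            {"n_patients": 2, "seed": 1, "complication_rate": 1.5},
            {"n_patients": 2, "seed": 1, "corruption_split": (0.5, 0.5, 0.5)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GeneratorParams(**kwargs)

    def test_empty_template_bank_rejected(self):
        params = GeneratorParams(
            n_patients=1, seed=1, template_bank={"clinical_complete": []}
        )
        with pytest.raises(ConfigurationError):
            generate_corpus(params)


class TestGenerateCorpus:
    def test_deterministic_under_seed(self):
        params = GeneratorParams(n_patients=8, seed=42)
        assert generate_corpus(params) == generate_corpus(params)

    def test_distinct_seeds_differ(self):
        notes1, _ = generate_corpus(GeneratorParams(n_patients=8, seed=1))
        notes2, _ = generate_corpus(GeneratorParams(n_patients=8, seed=2))
        assert [n.text for n in notes1] != [n.text for n in notes2]

    def test_gold_cardinality_and_validity(self):
        _, gold = generate_corpus(GeneratorParams(n_patients=12, seed=7))
        assert len(gold) == 24
        for g in gold:
            if g.triple is not None:
                p, s, t = g.triple
                assert p in range(3, 6) and s in range(3, 6) and p + s == t
            if g.corruption != "none":
                assert g.expected_triage == "complicated"

    def test_surgery_total_upgraded_over_biopsy(self):
        _, gold = generate_corpus(
            GeneratorParams(n_patients=40, seed=3, p_upgrade=1.0)
        )
        by_patient = {}
        for g in gold:
            by_patient.setdefault(g.patient_id, {})[g.specimen_type] = g.triple
        pairs = [
            (p["biopsy"], p["surgery"])
            for p in by_patient.values()
            if p["surgery"] is not None
        ]
        assert pairs, "some patients must have surgery"
        assert all(surgery[2] >= biopsy[2] for biopsy, surgery in pairs)

    def test_every_scored_note_has_an_anchor(self, lex):
        notes, gold = generate_corpus(GeneratorParams(n_patients=10, seed=9))
        scored_patients = {g.patient_id for g in gold if g.triple is not None}
        for pid in scored_patients:
            texts = [n.text for n in notes if n.patient_id == pid]
            assert any("gleason" in t.lower() or "gs" in t.lower() for t in texts)

    def test_clean_corpus_round_trip_is_exact(self):
        """With no corruption injected, the pipeline recovers every gold
        triple and flags nothing (label-consistency invariant)."""
        notes, gold = generate_corpus(
            GeneratorParams(n_patients=30, seed=11, complication_rate=0.0)
        )
        records, queue, _ = run_extract(notes)
        assert queue == []
        by_patient = {r.patient_id: r for r in records}
        for g in gold:
            record = by_patient[g.patient_id]
            score = (
                record.surgery_score if g.specimen_type == "surgery" else record.biopsy_score
            )
            predicted = None if score is None else score.astuple()
            assert predicted == g.triple

    def test_injected_corruptions_detected_with_matching_reason(self):
        """Every corrupted task is triaged complicated with the expected
        complication reason; clean tasks stay uncomplicated."""
        notes, gold = generate_corpus(
            GeneratorParams(n_patients=50, seed=13, complication_rate=0.3)
        )
        _, _, tasks = run_extract(notes)
        by_key = {(t.patient_id, t.specimen_type): t for t in tasks}
        n_corrupted = 0
        for g in gold:
            task = by_key[(g.patient_id, g.specimen_type)]
            if g.corruption != "none":
                n_corrupted += 1
                assert task.triage is Triage.COMPLICATED
                assert REASON_OF[g.corruption] in task.reasons
            else:
                assert task.triage is Triage.UNCOMPLICATED
        assert n_corrupted >= 10

    def test_complication_count_tracks_configured_rate(self):
        """Aggregated over seeds, the injected-complication count stays
        within 4 sigma of its binomial expectation."""
        n, rate, seeds = 50, 0.05, range(20)
        total = 0
        tasks = 0
        for seed in seeds:
            _, gold = generate_corpus(
                GeneratorParams(n_patients=n, seed=seed, complication_rate=rate)
            )
            scored = [g for g in gold if g.triple is not None]
            total += sum(g.expected_triage == "complicated" for g in scored)
            tasks += len(scored)
        expected = tasks * rate
        sigma = (tasks * rate * (1 - rate)) ** 0.5
        assert abs(total - expected) <= 4 * sigma


class TestInjectComplication:
    def base_note(self, text="Gleason 3+4=7 on PNBx."):
        return Note("P1", "N1", "clinical", text, "2018-03-01")

    def base_gold(self, specimen="biopsy"):
        return GoldLabel("P1", specimen, (3, 4, 7))

    def test_inaccurate_sum_perturbs_rendered_total(self):
        rng = np.random.default_rng(0)
        note, gold = inject_complication(
            self.base_note(), self.base_gold(), "inaccurate_sum", rng
        )
        assert "3+4=8" in note.text
        assert gold.expected_triage == "complicated"
        (mention,) = extract_note(note)
        assert mention.validity is Validity.INACCURATE

    def test_inaccurate_sum_handles_parenthesized_grammar(self):
        rng = np.random.default_rng(0)
        note, _ = inject_complication(
            self.base_note("GS 7 (3+4) on PNBx."), self.base_gold(), "inaccurate_sum", rng
        )
        assert "8 (3+4)" in note.text

    def test_missing_component_leaves_only_primary(self):
        rng = np.random.default_rng(0)
        note, gold = inject_complication(
            self.base_note(), self.base_gold(), "missing_component", rng
        )
        (mention,) = extract_note(note)
        assert mention.triple.astuple() == (3, None, None)
        assert mention.validity is Validity.INCOMPLETE
        assert gold.expected_triage == "complicated"

    def test_cross_note_conflict_emits_second_valid_note(self):
        rng = np.random.default_rng(0)
        original = self.base_note()
        conflict, gold = inject_complication(
            original, self.base_gold(), "cross_note_conflict", rng
        )
        assert conflict.note_id != original.note_id
        assert conflict.note_type == "clinical"
        (mention,) = extract_note(conflict)
        assert mention.validity is Validity.VALID
        assert mention.triple.astuple() != (3, 4, 7)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            inject_complication(
                self.base_note(), self.base_gold(), "typo", np.random.default_rng(0)
            )

    def test_all_kinds_are_exercised_by_the_generator(self):
        _, gold = generate_corpus(
            GeneratorParams(n_patients=80, seed=21, complication_rate=0.4)
        )
        seen = {g.corruption for g in gold if g.corruption != "none"}
        assert seen == set(CORRUPTIONS)
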