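import pytest

from gleason_nlp import Note, default_lexicon


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture
def clinical_note():
    def make(text, patient_id="P1", note_id="N1"):
        return Note(patient_id=patient_id, note_id=note_id, note_type="clinical", text=text)

    return make


@pytest.fixture
def pathology_note():
    def make(text, patient_id="P1", note_id="N1"):
        return Note(patient_id=patient_id, note_id=note_id, note_type="pathology", text=text)

    return make
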