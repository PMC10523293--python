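import pytest

from housinglens.addresses import ResourceDirectory
from housinglens.linker import ConceptVocabulary
from housinglens.notes import Lexicon
from housinglens.pipeline import _default_directory_path
from housinglens.records import ClinicalNote


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return Lexicon.default()


@pytest.fixture(scope="session")
def directory() -> ResourceDirectory:
    return ResourceDirectory.from_csv(_default_directory_path())


@pytest.fixture(scope="session")
def vocab() -> ConceptVocabulary:
    return ConceptVocabulary.default()


@pytest.fixture
def make_note():
    def _make(text: str, note_id: str = "N1", patient_id: str = "P1") -> ClinicalNote:
        return ClinicalNote(note_id=note_id, patient_id=patient_id, date="2019-01-01", text=text)

    return _make
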