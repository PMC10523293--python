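"""Dictionary NER over a concept vocabulary plus a knowledgebase linker.

The reference recognizer is deterministic longest-match dictionary scanning
over 1-5 token windows.  Candidate spans come from the vocabulary surface
forms plus an extra set of entity patterns, which emulates a trained
recognizer that can detect phrases the target vocabulary cannot code.
Linking is normalized-exact only: a recognized span either resolves to a
concept or is counted as ``recognized_unlinked`` — the characteristic
precision/recall trade of dictionary linking, which this module preserves on
purpose rather than papering over with fuzzy matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable

import pandas as pd

from housinglens._util import token_tuple, tokenize
from housinglens.notes import (
    DEFAULT_EVIDENCE_STATUSES,
    Lexicon,
    Mention,
    _scan_phrases,
    _sentence_index,
    build_phrase_index,
    qualify,
    segment,
)
from housinglens.records import ClinicalNote, EvidenceFlag

MAX_WINDOW = 5

#: Housing phrasings the recognizer detects but the fixture vocabulary cannot
#: code; these exercise the recognized_unlinked path.
DEFAULT_ENTITY_PATTERNS = (
    "couch surfing",
    "sleeping rough",
    "living out of a car",
    "doubling up with relatives",
)


@dataclass(frozen=True)
class Concept:
    concept_id: str
    preferred_term: str
    synonyms: tuple[str, ...]
    housing_related: bool


@dataclass(frozen=True)
class ConceptMatch:
    note_id: str
    start: int
    end: int
    surface: str
    concept_id: str | None
    housing_related: bool
    link_outcome: str  # linked | recognized_unlinked

    def __post_init__(self) -> None:
        if self.link_outcome == "linked" and self.concept_id is None:
            raise ValueError("linked match requires a concept_id")
        if self.link_outcome == "recognized_unlinked" and self.concept_id is not None:
            raise ValueError("unlinked match must not carry a concept_id")


@dataclass
class ConceptVocabulary:
    """Concept entries plus a surface-form index for normalized-exact lookup.

    Every surface form (preferred term or synonym) maps to exactly one
    concept; collisions are rejected at load time.
    """

    concepts: list[Concept]
    _index: dict[tuple[str, ...], Concept] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for concept in self.concepts:
            for surface in (concept.preferred_term, *concept.synonyms):
                form = token_tuple(surface)
                if not form:
                    raise ValueError(f"empty surface form in {concept.concept_id}")
                owner = self._index.get(form)
                if owner is not None and owner.concept_id != concept.concept_id:
                    raise ValueError(
                        f"surface form {surface!r} maps to both "
                        f"{owner.concept_id} and {concept.concept_id}"
                    )
                self._index[form] = concept
        if self.concepts:
            self._max_len = min(MAX_WINDOW, max(len(f) for f in self._index))
        else:
            self._max_len = 0

    def lookup(self, surface: str) -> Concept | None:
        return self._index.get(token_tuple(surface))

    def surface_tuples(self) -> set[tuple[str, ...]]:
        return {f for f in self._index if len(f) <= MAX_WINDOW}

    def __len__(self) -> int:
        return len(self.concepts)

    @classmethod
    def from_tsv(cls, path) -> "ConceptVocabulary":
        """Load the vocabulary file: concept_id <TAB> preferred_term <TAB>
        synonyms (pipe-delimited) <TAB> housing_related (0/1)."""
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        concepts = [
            Concept(
                concept_id=row.concept_id,
                preferred_term=row.preferred_term,
                synonyms=tuple(s.strip() for s in row.synonyms.split("|") if s.strip()),
                housing_related=str(row.housing_related) in ("1", "true", "True"),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(concepts)

    @classmethod
    def default(cls) -> "ConceptVocabulary":
        with resources.as_file(
            resources.files("housinglens.data").joinpath("vocabulary.tsv")
        ) as path:
            return cls.from_tsv(path)


def build_entity_index(
    vocab: ConceptVocabulary,
    entity_patterns: Iterable[str] = DEFAULT_ENTITY_PATTERNS,
) -> dict[str, list[tuple[str, ...]]]:
    """Combined candidate index: vocabulary surface forms + extra patterns."""
    phrase_set = vocab.surface_tuples()
    for pattern in entity_patterns:
        form = token_tuple(pattern)
        if form and len(form) <= MAX_WINDOW:
            phrase_set.add(form)
    return build_phrase_index(phrase_set)


def extract_entities(
    note: ClinicalNote,
    vocab: ConceptVocabulary,
    entity_patterns: Iterable[str] = DEFAULT_ENTITY_PATTERNS,
    recognizer: Callable[[str], list[tuple[int, int]]] | None = None,
    *,
    entity_index: dict[str, list[tuple[str, ...]]] | None = None,
) -> list[tuple[int, int]]:
    """Candidate entity spans (character offsets, half-open).

    Default: greedy longest-match dictionary scan (1-5 token windows) over
    vocabulary surface forms plus ``entity_patterns``.  Passing ``recognizer``
    swaps in an external model producing spans of identical shape;
    ``entity_index`` short-circuits index building for batch callers.
    """
    if recognizer is not None:
        return recognizer(note.text)
    if entity_index is None:
        entity_index = build_entity_index(vocab, entity_patterns)
    if not entity_index:
        return []
    tokens = tokenize(note.text)
    return [
        (tokens[first][1], tokens[last][2])
        for first, last in _scan_phrases(tokens, entity_index)
    ]


def link_entity(
    note_id: str, start: int, end: int, surface: str, vocab: ConceptVocabulary
) -> ConceptMatch:
    """Normalized-exact lookup of one recognized span."""
    if not surface:
        raise ValueError("cannot link an empty surface")
    concept = vocab.lookup(surface)
    if concept is None:
        return ConceptMatch(
            note_id=note_id,
            start=start,
            end=end,
            surface=surface,
            concept_id=None,
            housing_related=False,
            link_outcome="recognized_unlinked",
        )
    return ConceptMatch(
        note_id=note_id,
        start=start,
        end=end,
        surface=surface,
        concept_id=concept.concept_id,
        housing_related=concept.housing_related,
        link_outcome="linked",
    )


def link_note(
    note: ClinicalNote,
    vocab: ConceptVocabulary,
    entity_patterns: Iterable[str] = DEFAULT_ENTITY_PATTERNS,
    recognizer: Callable[[str], list[tuple[int, int]]] | None = None,
    *,
    entity_index: dict[str, list[tuple[str, ...]]] | None = None,
) -> list[ConceptMatch]:
    """Recognize and link every candidate span in one note."""
    return [
        link_entity(note.note_id, start, end, note.text[start:end], vocab)
        for start, end in extract_entities(
            note, vocab, entity_patterns, recognizer, entity_index=entity_index
        )
    ]


def detect_housing_concepts(
    note: ClinicalNote,
    vocab: ConceptVocabulary,
    lexicon: Lexicon,
    *,
    patient_id: str | None = None,
    entity_patterns: Iterable[str] = DEFAULT_ENTITY_PATTERNS,
    evidence_statuses: frozenset[str] = DEFAULT_EVIDENCE_STATUSES,
    entity_index: dict[str, list[tuple[str, ...]]] | None = None,
) -> tuple[EvidenceFlag | None, list[ConceptMatch]]:
    """NER-channel evidence: a flag iff some linked housing concept survives
    qualification (negated / third-party matches are discounted)."""
    matches = link_note(note, vocab, entity_patterns, entity_index=entity_index)
    sentences = segment(note.text)
    flag = None
    for match in matches:
        if match.link_outcome != "linked" or not match.housing_related:
            continue
        mention = Mention(
            note_id=note.note_id,
            method="ner",
            surface=match.surface,
            start=match.start,
            end=match.end,
            sentence_index=_sentence_index(sentences, match.start),
        )
        status = qualify(mention, note.text, lexicon)
        if status in evidence_statuses and flag is None:
            flag = EvidenceFlag(
                patient_id=patient_id if patient_id is not None else note.patient_id,
                source="note",
                method="ner",
                provenance=f"{note.note_id}:{match.start}-{match.end}",
            )
    return flag, matches
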