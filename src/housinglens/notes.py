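"""Note-channel evidence: lexicon keyword matching with negation / history /
experiencer qualification, and shelter-by-name matching.

Qualification is window-based (NegEx-style): a cue within ``window`` tokens
of the match, inside the same sentence, changes the mention status.  Negation
cues are honored both before and after the match ("asked if she was homeless
and she denied"); history and third-party cues must precede.  Precedence:
negated > third_party > historical > affirmed.

Shelter-name mentions are never negation-qualified: even an indirect or
negated mention of a shelter signals that a provider perceived a housing
need.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from housinglens._util import token_tuple, tokenize
from housinglens.addresses import ResourceDirectory
from housinglens.records import ClinicalNote, EvidenceFlag, Mention

DEFAULT_WINDOW = 6

_SENT_SPLIT = re.compile(r"(?<=[.!?;])\s+|\n+")


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    text: str


@dataclass
class Lexicon:
    """Housing terms plus qualification cue lists.  All matching is
    token-sequence based and case-insensitive."""

    terms: list[str]
    negation_pre: list[str]
    negation_post: list[str]
    history_cues: list[str]
    third_party_cues: list[str]
    window: int = DEFAULT_WINDOW
    _term_index: set[tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lexicon has no housing terms")
        self._term_index = {token_tuple(t) for t in self.terms}
        self._max_len = max(len(t) for t in self._term_index)
        self._phrase_index = build_phrase_index(self._term_index)

    def term_tuples(self) -> set[tuple[str, ...]]:
        return set(self._term_index)

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            terms=raw["terms"],
            negation_pre=raw["negation_pre"],
            negation_post=raw["negation_post"],
            history_cues=raw["history_cues"],
            third_party_cues=raw["third_party_cues"],
            window=int(raw.get("window", DEFAULT_WINDOW)),
        )

    @classmethod
    def default(cls) -> "Lexicon":
        with resources.as_file(
            resources.files("housinglens.data").joinpath("lexicon.yaml")
        ) as path:
            return cls.from_yaml(path)


def segment(text: str) -> list[Sentence]:
    """Rule-based sentence splitting on punctuation runs and newlines.

    Each sentence carries exact character offsets: ``text[s.start:s.end] ==
    s.text`` for every returned sentence.
    """
    sentences: list[Sentence] = []
    pos = 0

    def add(start: int, end: int) -> None:
        chunk = text[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        s, e = start + lead, end - trail
        if e > s:
            sentences.append(Sentence(s, e, text[s:e]))

    for m in _SENT_SPLIT.finditer(text):
        add(pos, m.start())
        pos = m.end()
    add(pos, len(text))
    return sentences


def build_phrase_index(
    phrase_set: set[tuple[str, ...]],
) -> dict[str, list[tuple[str, ...]]]:
    """First-token index for the phrase scanner, longest phrases first."""
    index: dict[str, list[tuple[str, ...]]] = {}
    for phrase in phrase_set:
        index.setdefault(phrase[0], []).append(phrase)
    for options in index.values():
        options.sort(key=len, reverse=True)
    return index


def _scan_phrases(
    tokens: list[tuple[str, int, int]],
    phrase_index: dict[str, list[tuple[str, ...]]],
) -> list[tuple[int, int]]:
    """Greedy left-to-right longest-match scan.

    Returns non-overlapping ``(first_token_idx, last_token_idx)`` pairs;
    shorter matches overlapping a longer one are suppressed.
    """
    lower = [t[0].lower() for t in tokens]
    hits: list[tuple[int, int]] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = 0
        for phrase in phrase_index.get(lower[i], ()):
            length = len(phrase)
            if i + length <= n and tuple(lower[i : i + length]) == phrase:
                matched = length
                break
        if matched:
            hits.append((i, i + matched - 1))
            i += matched
        else:
            i += 1
    return hits


def _sentence_index(sentences: list[Sentence], offset: int) -> int:
    starts = [s.start for s in sentences]
    idx = bisect.bisect_right(starts, offset) - 1
    return max(idx, 0)


def match_keywords(note: ClinicalNote, lexicon: Lexicon) -> list[Mention]:
    """One mention per non-overlapping longest lexicon match."""
    tokens = tokenize(note.text)
    sentences = segment(note.text)
    mentions = []
    for first, last in _scan_phrases(tokens, lexicon._phrase_index):
        start, end = tokens[first][1], tokens[last][2]
        mentions.append(
            Mention(
                note_id=note.note_id,
                method="keyword",
                surface=note.text[start:end],
                start=start,
                end=end,
                sentence_index=_sentence_index(sentences, start),
            )
        )
    return mentions


def _cue_positions(
    tokens: list[tuple[str, int, int]], cues: list[str]
) -> list[tuple[int, int]]:
    positions = []
    for cue in cues:
        cue_tokens = token_tuple(cue)
        n = len(cue_tokens)
        for i in range(len(tokens) - n + 1):
            if tuple(t[0].lower() for t in tokens[i : i + n]) == cue_tokens:
                positions.append((i, i + n - 1))
    return positions


def qualify(mention: Mention, note_text: str, lexicon: Lexicon) -> str:
    """Status of a mention from cues inside its sentence.

    Negation cues count before or after the match; history and third-party
    cues only before.  Cue scope never crosses sentence breaks.
    """
    sentences = segment(note_text)
    sent = sentences[mention.sentence_index]
    if not (sent.start <= mention.start and mention.end <= sent.end):
        raise ValueError("mention span lies outside its sentence")
    tokens = tokenize(sent.text)
    rel_start = mention.start - sent.start
    rel_end = mention.end - sent.start
    in_span = [i for i, t in enumerate(tokens) if t[1] >= rel_start and t[2] <= rel_end]
    if not in_span:
        return "affirmed"
    m_first, m_last = in_span[0], in_span[-1]
    w = lexicon.window

    def before(cue_first: int, cue_last: int) -> bool:
        return cue_last < m_first and (m_first - cue_last) <= w

    def after(cue_first: int, cue_last: int) -> bool:
        return cue_first > m_last and (cue_first - m_last) <= w

    for first, last in _cue_positions(tokens, lexicon.negation_pre):
        if before(first, last):
            return "negated"
    for first, last in _cue_positions(tokens, lexicon.negation_post):
        if after(first, last) or before(first, last):
            return "negated"
    for first, last in _cue_positions(tokens, lexicon.third_party_cues):
        if before(first, last):
            return "third_party"
    for first, last in _cue_positions(tokens, lexicon.history_cues):
        if before(first, last):
            return "historical"
    return "affirmed"


def build_shelter_index(
    directory: ResourceDirectory, lexicon: Lexicon
) -> dict[tuple[str, ...], str]:
    """Token-sequence index of resource names/aliases -> resource_id.

    A name or alias identical to a lexicon keyword would make shelter counts
    and keyword counts indistinguishable, so that collision is rejected at
    load time.
    """
    index: dict[tuple[str, ...], str] = {}
    term_set = lexicon.term_tuples()
    for form, resource_id in directory.surface_forms():
        if not form:
            raise ValueError(f"resource {resource_id} has an empty surface form")
        if form in term_set:
            raise ValueError(
                f"resource surface form {' '.join(form)!r} collides with a lexicon keyword"
            )
        index[form] = resource_id
    return index


@dataclass
class ShelterMatcher:
    """Prebuilt token-sequence matcher over shelter names and aliases."""

    rid_by_form: dict[tuple[str, ...], str]
    phrase_index: dict[str, list[tuple[str, ...]]]

    @classmethod
    def build(
        cls, directory: ResourceDirectory, lexicon: Lexicon | None = None
    ) -> "ShelterMatcher":
        if lexicon is not None:
            index = build_shelter_index(directory, lexicon)
        else:
            index = {form: rid for form, rid in directory.surface_forms()}
        return cls(rid_by_form=index, phrase_index=build_phrase_index(set(index)))

    def match(self, note: ClinicalNote) -> list[Mention]:
        if not self.rid_by_form:
            return []
        tokens = tokenize(note.text)
        sentences = segment(note.text)
        mentions = []
        for first, last in _scan_phrases(tokens, self.phrase_index):
            start, end = tokens[first][1], tokens[last][2]
            surface = note.text[start:end]
            mentions.append(
                Mention(
                    note_id=note.note_id,
                    method="shelter_name",
                    surface=surface,
                    start=start,
                    end=end,
                    sentence_index=_sentence_index(sentences, start),
                    status="affirmed",
                    resource_id=self.rid_by_form[token_tuple(surface)],
                )
            )
        return mentions


def match_shelters(
    note: ClinicalNote, directory: ResourceDirectory, lexicon: Lexicon | None = None
) -> list[Mention]:
    """Case-insensitive token-sequence matches of shelter names and aliases.

    Indirect mentions (information-giving, transport) match like any other;
    shelter mentions always carry status ``affirmed``.
    """
    return ShelterMatcher.build(directory, lexicon).match(note)


#: mention statuses that yield evidence under the default configuration
DEFAULT_EVIDENCE_STATUSES = frozenset({"affirmed", "historical"})


def extract_note_evidence(
    note: ClinicalNote,
    lexicon: Lexicon,
    directory: ResourceDirectory | None = None,
    *,
    patient_id: str | None = None,
    evidence_statuses: frozenset[str] = DEFAULT_EVIDENCE_STATUSES,
    shelter_matcher: ShelterMatcher | None = None,
) -> tuple[list[Mention], list[EvidenceFlag]]:
    """Keyword + shelter mentions for one note, with the flags they yield.

    Historical mentions count as evidence by default (no temporal filter);
    third-party mentions are excluded by default; both are configurable via
    ``evidence_statuses``.
    """
    pid = patient_id if patient_id is not None else note.patient_id
    mentions: list[Mention] = []
    flags: list[EvidenceFlag] = []
    for mention in match_keywords(note, lexicon):
        status = qualify(mention, note.text, lexicon)
        qualified = replace(mention, status=status)
        mentions.append(qualified)
        if status in evidence_statuses:
            flags.append(
                EvidenceFlag(
                    patient_id=pid,
                    source="note",
                    method="keyword",
                    provenance=f"{note.note_id}:{mention.start}-{mention.end}",
                )
            )
    if shelter_matcher is None and directory is not None:
        shelter_matcher = ShelterMatcher.build(directory, lexicon)
    if shelter_matcher is not None:
        for mention in shelter_matcher.match(note):
            mentions.append(mention)
            flags.append(
                EvidenceFlag(
                    patient_id=pid,
                    source="note",
                    method="shelter_name",
                    provenance=f"{note.note_id}:{mention.start}-{mention.end}",
                )
            )
    return mentions, flags
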