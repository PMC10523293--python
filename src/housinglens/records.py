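"""Shared record types used across the detection channels.

These are deliberately plain dataclasses: every channel reads and writes the
documented text formats (CSV / JSONL), so the in-memory types stay thin and
serializable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Evidence sources, in reporting order.
SOURCES = ("diagnosis", "address", "note")

#: Detection method -> the unique source it belongs to.
METHOD_SOURCE = {
    "icd_z59": "diagnosis",
    "resource_address": "address",
    "literal_homeless": "address",
    "keyword": "note",
    "shelter_name": "note",
    "ner": "note",
}


@dataclass(frozen=True)
class Encounter:
    """One billed encounter: a patient, a date, and one ICD-10-CM code."""

    encounter_id: str
    patient_id: str
    date: str  # ISO yyyy-mm-dd
    code: str


@dataclass(frozen=True)
class AddressRecord:
    """Semi-structured address as captured by the EHR."""

    patient_id: str
    line1: str
    line2: str
    city: str
    state: str
    zip: str
    date: str = ""  # optional effective date; latest record wins

    def __post_init__(self) -> None:
        if not (self.line1.strip() or self.city.strip()):
            raise ValueError(
                f"address for {self.patient_id!r}: line1 and city are both empty"
            )


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    date: str
    text: str


@dataclass
class PatientRecord:
    """One patient with demographics, tract, and attached source records."""

    patient_id: str
    sex: str
    race: str
    age_band: str
    tract: str
    encounters: list[Encounter] = field(default_factory=list)
    addresses: list[AddressRecord] = field(default_factory=list)
    notes: list[ClinicalNote] = field(default_factory=list)


@dataclass(frozen=True)
class ResourceEntry:
    """A community housing resource: shelter, transitional housing, or
    residential SUD treatment facility."""

    resource_id: str
    name: str
    aliases: tuple[str, ...]
    address_key: str
    roles: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError(f"resource {self.resource_id!r} has an empty name")


@dataclass(frozen=True)
class EvidenceFlag:
    """One piece of housing-instability evidence with provenance."""

    patient_id: str
    source: str
    method: str
    provenance: str

    def __post_init__(self) -> None:
        expected = METHOD_SOURCE.get(self.method)
        if expected is None:
            raise ValueError(f"unknown evidence method {self.method!r}")
        if self.source != expected:
            raise ValueError(
                f"method {self.method!r} implies source {expected!r}, got {self.source!r}"
            )


@dataclass(frozen=True)
class Mention:
    """A matched housing mention inside one note.

    ``start``/``end`` are 0-based, half-open character offsets into the note
    text; the slice at the span equals ``surface`` up to case.
    """

    note_id: str
    method: str  # keyword | shelter_name | ner
    surface: str
    start: int
    end: int
    sentence_index: int
    status: str = "affirmed"  # affirmed | negated | historical | third_party
    resource_id: str | None = None


@dataclass
class GroundTruth:
    """Planted truth for one synthetic patient."""

    patient_id: str
    housing_unstable: bool
    documented_via: set[str] = field(default_factory=set)
    noise_sources: set[str] = field(default_factory=set)
    # (note_id, label, rendered sentence) per planted mention
    mention_labels: list[tuple[str, str, str]] = field(default_factory=list)
    oov_planted: bool = False
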