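"""ICD-10-CM prefix matching: SUD cohorts, poisoning episodes, and
diagnosis-code housing evidence.

Matching is dot-stripped prefix comparison: billing extracts vary in whether
they carry the decimal point, so both the pattern stem and the input code are
reduced to one canonical dotless uppercase form before comparison.  A trailing
``*`` on a pattern is cosmetic and ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from housinglens.records import Encounter, EvidenceFlag

log = logging.getLogger(__name__)

_VALID_PREFIX = re.compile(r"^[A-Z0-9.]+$")
_seen_malformed: set[str] = set()


@dataclass(frozen=True)
class CodePattern:
    """An ICD-10-CM code stem with a semantic tag."""

    prefix: str
    label: str

    def __post_init__(self) -> None:
        stem = self.prefix.rstrip("*")
        if not stem or not _VALID_PREFIX.match(stem):
            raise ValueError(f"invalid code prefix {self.prefix!r}")


# Default pattern sets; sites can extend these without code changes via the
# run configuration.
STIMULANT_PATTERNS = tuple(
    CodePattern(p, "stimulant") for p in ("F14.*", "F15.*", "T40.5*", "T43.6*")
)
OPIOID_PATTERNS = tuple(
    CodePattern(p, "opioid")
    for p in ("F11.*", "T40.0*", "T40.1*", "T40.2*", "T40.3*", "T40.4*", "T40.6*")
)
HOUSING_PATTERNS = (CodePattern("Z59*", "housing"),)
POISONING_PATTERNS = (
    CodePattern("T40.*", "poisoning_opioid"),
    CodePattern("T43.6*", "poisoning_stimulant"),
)

SUD_TYPES = ("stimulant_only", "opioid_only", "both", "none")


def _canon(code: str) -> str:
    return code.replace(".", "").strip().upper()


def match_code(code: str, pattern: CodePattern) -> bool:
    """True iff the dot-stripped code starts with the pattern's stem.

    ``"T40.5*"`` therefore matches full 7-character billing codes such as
    ``"T40.5X1A"``.  Malformed codes never match and are logged once per
    distinct value.
    """
    if not code or not code.strip():
        raise ValueError("empty ICD code")
    canon = _canon(code)
    if not _VALID_PREFIX.match(canon):
        if code not in _seen_malformed:
            _seen_malformed.add(code)
            log.warning("malformed ICD code %r ignored", code)
        return False
    return canon.startswith(_canon(pattern.prefix.rstrip("*")))


def _any_match(code: str, patterns: tuple[CodePattern, ...]) -> bool:
    return any(match_code(code, p) for p in patterns)


def classify_sud(encounters: list[Encounter]) -> str:
    """Three-way SUD cohort: stimulant_only / opioid_only / both / none.

    Order- and duplication-invariant: only the set of codes matters.
    """
    stim = any(_any_match(e.code, STIMULANT_PATTERNS) for e in encounters)
    opi = any(_any_match(e.code, OPIOID_PATTERNS) for e in encounters)
    if stim and opi:
        return "both"
    if stim:
        return "stimulant_only"
    if opi:
        return "opioid_only"
    return "none"


def detect_housing_code(encounters: list[Encounter]) -> EvidenceFlag | None:
    """Z59* housing-evidence flag, with provenance on the earliest match."""
    hits = [e for e in encounters if _any_match(e.code, HOUSING_PATTERNS)]
    if not hits:
        return None
    first = min(hits, key=lambda e: (e.date, e.encounter_id))
    return EvidenceFlag(
        patient_id=first.patient_id,
        source="diagnosis",
        method="icd_z59",
        provenance=f"{first.encounter_id}:{first.code}",
    )


def detect_poisoning(encounters: list[Encounter]) -> bool:
    """True iff any code matches T40.* or T43.6* (overdose-related event)."""
    return any(_any_match(e.code, POISONING_PATTERNS) for e in encounters)
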