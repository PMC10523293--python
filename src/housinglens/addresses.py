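"""Address-channel evidence: normalization, curated-resource matching,
literal-homeless lines, and generic-address flagging.

Evidence comes from two places only: an address that matches the curated
community-resource directory, or a literal "homeless"-type first address
line.  Generic placeholder addresses ("Lexington, KY" with no street line)
are counted descriptively but never emitted as evidence — a missing address
does not by itself imply a housing issue.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from housinglens._util import edit_similarity, token_tuple
from housinglens.records import AddressRecord, EvidenceFlag, ResourceEntry

log = logging.getLogger(__name__)

# USPS-style street suffix abbreviations (already-abbreviated forms pass
# through untouched, which keeps normalization idempotent).
_SUFFIXES = {
    "STREET": "ST",
    "AVENUE": "AVE",
    "ROAD": "RD",
    "DRIVE": "DR",
    "LANE": "LN",
    "BOULEVARD": "BLVD",
    "COURT": "CT",
    "PLACE": "PL",
    "CIRCLE": "CIR",
    "TERRACE": "TER",
    "PARKWAY": "PKWY",
    "HIGHWAY": "HWY",
    "SQUARE": "SQ",
    "TRAIL": "TRL",
    "PIKE": "PIKE",
    "WAY": "WAY",
}

# Unit designators: the designator and its following token are dropped.
_UNIT_WORDS = {"APT", "APARTMENT", "STE", "SUITE", "UNIT", "RM", "ROOM", "BLDG", "FL", "FLOOR"}

#: Placeholder strings treated as "no address line given".
DEFAULT_PLACEHOLDERS = ("UNKNOWN", "UNK", "NONE", "N/A", "NA", "XX", "NEEDS UPDATE")

#: line1 tokens/phrases treated as a literal homelessness declaration.
DEFAULT_LITERAL_TERMS = ("homeless", "unhoused", "no address")

_WORD_RE = re.compile(r"#?[A-Z0-9'\-]+|#")


def _norm_line(text: str) -> str:
    """Uppercase, strip punctuation, abbreviate suffixes, drop unit designators."""
    upper = re.sub(r"[^\w#\s'-]", " ", text.upper())
    tokens = _WORD_RE.findall(upper)
    out: list[str] = []
    skip_next = False
    for tok in tokens:
        if skip_next:
            skip_next = False
            continue
        if tok.startswith("#"):
            if tok == "#":
                skip_next = True
            continue
        if tok in _UNIT_WORDS:
            skip_next = True
            continue
        out.append(_SUFFIXES.get(tok, tok))
    return " ".join(out)


def normalize_address(rec: AddressRecord) -> str:
    """Canonical matching key ``line1|city|state|zip5``.

    Idempotent: feeding a key's segments back through produces the same key.
    """
    return "|".join(
        (
            _norm_line(rec.line1),
            _norm_line(rec.city),
            rec.state.strip().upper(),
            re.sub(r"\D", "", rec.zip)[:5],
        )
    )


@dataclass
class ResourceDirectory:
    """Curated community-resource list with a pre-normalized address index."""

    entries: list[ResourceEntry]
    _by_key: dict[str, ResourceEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_key = {}
        for entry in self.entries:
            if entry.address_key in self._by_key:
                raise ValueError(
                    f"duplicate normalized address key {entry.address_key!r} "
                    f"({entry.resource_id} vs {self._by_key[entry.address_key].resource_id})"
                )
            self._by_key[entry.address_key] = entry

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, key: str) -> ResourceEntry | None:
        return self._by_key.get(key)

    def keys(self) -> list[str]:
        return list(self._by_key)

    def surface_forms(self) -> list[tuple[tuple[str, ...], str]]:
        """(token sequence, resource_id) for every canonical name and alias."""
        forms = []
        for entry in self.entries:
            for name in (entry.name, *entry.aliases):
                forms.append((token_tuple(name), entry.resource_id))
        return forms

    @classmethod
    def from_csv(cls, path) -> "ResourceDirectory":
        """Load the directory CSV: resource_id, name, aliases (pipe-delimited),
        line1, city, state, zip, roles (pipe-delimited)."""
        frame = pd.read_csv(path, dtype=str).fillna("")
        entries = []
        for row in frame.itertuples(index=False):
            key = normalize_address(
                AddressRecord(
                    patient_id="",
                    line1=row.line1,
                    line2="",
                    city=row.city,
                    state=row.state,
                    zip=row.zip,
                )
            )
            aliases = tuple(a.strip() for a in row.aliases.split("|") if a.strip())
            roles = frozenset(r.strip() for r in row.roles.split("|") if r.strip())
            entries.append(
                ResourceEntry(
                    resource_id=row.resource_id,
                    name=row.name,
                    aliases=aliases,
                    address_key=key,
                    roles=roles,
                )
            )
        return cls(entries)


def match_resource(
    key: str,
    directory: ResourceDirectory,
    *,
    fuzzy: bool = True,
    threshold: float = 0.92,
) -> ResourceEntry | None:
    """Resolve a normalized address key against the directory.

    Exact key match first; optionally a fuzzy pass at the given normalized
    edit similarity.  Several distinct fuzzy candidates above threshold is an
    ambiguous match: warn and emit nothing.
    """
    exact = directory.get(key)
    if exact is not None:
        return exact
    if not fuzzy or not key.split("|", 1)[0]:
        return None
    candidates = []
    for cand_key in directory.keys():
        score = edit_similarity(key, cand_key, floor=threshold)
        if score >= threshold:
            candidates.append((score, cand_key))
    if not candidates:
        return None
    if len(candidates) > 1:
        log.warning("ambiguous fuzzy address match for %r: %s", key, candidates)
        return None
    score, cand_key = candidates[0]
    log.info("fuzzy address match %r -> %r (similarity %.3f)", key, cand_key, score)
    return directory.get(cand_key)


def flag_literal_homeless(
    rec: AddressRecord, literal_terms: tuple[str, ...] = DEFAULT_LITERAL_TERMS
) -> bool:
    """True iff line1 contains a literal homelessness token/phrase."""
    tokens = token_tuple(rec.line1)
    if not tokens:
        return False
    for term in literal_terms:
        term_tokens = token_tuple(term)
        n = len(term_tokens)
        if any(tokens[i : i + n] == term_tokens for i in range(len(tokens) - n + 1)):
            return True
    return False


def flag_generic(
    rec: AddressRecord, placeholders: tuple[str, ...] = DEFAULT_PLACEHOLDERS
) -> bool:
    """True iff both address lines are empty or placeholder while the city or
    state is present.  Generic addresses are descriptive only, never evidence."""
    placeholder_set = {p.upper() for p in placeholders}

    def is_blank(line: str) -> bool:
        stripped = line.strip().upper()
        return not stripped or stripped in placeholder_set

    return (
        is_blank(rec.line1)
        and is_blank(rec.line2)
        and bool(rec.city.strip() or rec.state.strip())
    )


def address_channel_summary(flags: list[EvidenceFlag]) -> dict:
    """Descriptive split of address-source evidence by method.

    ``literal_share_pct`` is the share of address-identified patients whose
    evidence is a literal "homeless" first address line.
    """
    from housinglens._util import pct

    address_flags = [f for f in flags if f.source == "address"]
    patients = {f.patient_id for f in address_flags}
    literal = {f.patient_id for f in address_flags if f.method == "literal_homeless"}
    resource = {f.patient_id for f in address_flags if f.method == "resource_address"}
    return {
        "address_total": len(patients),
        "literal_homeless": len(literal),
        "resource_address": len(resource),
        "literal_share_pct": pct(len(literal), len(patients)),
    }


def most_recent_address(records: list[AddressRecord]) -> AddressRecord | None:
    """The latest address by date; falls back to last-listed when undated."""
    if not records:
        return None
    return max(enumerate(records), key=lambda item: (item[1].date, item[0]))[1]


def evaluate_address(
    rec: AddressRecord,
    directory: ResourceDirectory,
    *,
    fuzzy: bool = True,
    threshold: float = 0.92,
    include_residential_treatment: bool = True,
    literal_terms: tuple[str, ...] = DEFAULT_LITERAL_TERMS,
    placeholders: tuple[str, ...] = DEFAULT_PLACEHOLDERS,
) -> tuple[EvidenceFlag | None, bool]:
    """Full address-channel decision for one record.

    Returns ``(evidence flag or None, generic?)``.  Resource matching takes
    priority over the literal-homeless check; generic records can never
    produce a flag (they carry no street line to match).
    """
    if flag_generic(rec, placeholders):
        return None, True
    key = normalize_address(rec)
    entry = match_resource(key, directory, fuzzy=fuzzy, threshold=threshold)
    if entry is not None:
        treatment_only = entry.roles == {"residential_sud_treatment"}
        if include_residential_treatment or not treatment_only:
            return (
                EvidenceFlag(
                    patient_id=rec.patient_id,
                    source="address",
                    method="resource_address",
                    provenance=f"{entry.resource_id}:{key}",
                ),
                False,
            )
    if flag_literal_homeless(rec, literal_terms):
        return (
            EvidenceFlag(
                patient_id=rec.patient_id,
                source="address",
                method="literal_homeless",
                provenance=key,
            ),
            False,
        )
    return None, False
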