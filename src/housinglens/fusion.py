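"""Evidence fusion: per-patient source sets, Venn partitioning, coverage
percentages, and census-tract aggregation.

Percentages are reported at one decimal place, round-half-up, matching the
granularity of the published result surfaces this layer mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from housinglens._util import pct
from housinglens.records import SOURCES, EvidenceFlag

UNKNOWN_TRACT = "unknown"


def fuse(
    flags: list[EvidenceFlag], patient_ids: list[str]
) -> dict[str, frozenset[str]]:
    """Patient -> subset of {diagnosis, address, note}.

    Every patient appears in the result (possibly with an empty set); a flag
    whose patient is not in ``patient_ids`` is a referential-integrity error.
    """
    known = set(patient_ids)
    sets: dict[str, set[str]] = {pid: set() for pid in patient_ids}
    for flag in flags:
        if flag.patient_id not in known:
            raise ValueError(f"evidence flag for unknown patient {flag.patient_id!r}")
        sets[flag.patient_id].add(flag.source)
    return {pid: frozenset(s) for pid, s in sets.items()}


@dataclass(frozen=True)
class VennPartition:
    """Counts for the 7 nonempty regions of D (diagnosis), A (address),
    N (notes)."""

    d_only: int
    a_only: int
    n_only: int
    da: int  # D and A, not N
    dn: int  # D and N, not A
    an: int  # A and N, not D
    dan: int  # all three

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.regions().values()):
            raise ValueError("Venn region counts must be nonnegative")

    def regions(self) -> dict[str, int]:
        return {
            "d_only": self.d_only,
            "a_only": self.a_only,
            "n_only": self.n_only,
            "da": self.da,
            "dn": self.dn,
            "an": self.an,
            "dan": self.dan,
        }

    @property
    def union(self) -> int:
        return sum(self.regions().values())

    @property
    def total_diagnosis(self) -> int:
        return self.d_only + self.da + self.dn + self.dan

    @property
    def total_address(self) -> int:
        return self.a_only + self.da + self.an + self.dan

    @property
    def total_note(self) -> int:
        return self.n_only + self.dn + self.an + self.dan

    @property
    def single_source(self) -> int:
        return self.d_only + self.a_only + self.n_only

    def totals(self) -> dict[str, int]:
        return {
            "diagnosis": self.total_diagnosis,
            "address": self.total_address,
            "note": self.total_note,
        }


def venn(source_sets: dict[str, frozenset[str]]) -> VennPartition:
    """Exact region counts from per-patient source sets."""
    counts = {key: 0 for key in ("d_only", "a_only", "n_only", "da", "dn", "an", "dan")}
    region_of = {
        frozenset({"diagnosis"}): "d_only",
        frozenset({"address"}): "a_only",
        frozenset({"note"}): "n_only",
        frozenset({"diagnosis", "address"}): "da",
        frozenset({"diagnosis", "note"}): "dn",
        frozenset({"address", "note"}): "an",
        frozenset({"diagnosis", "address", "note"}): "dan",
    }
    for sources in source_sets.values():
        if sources:
            counts[region_of[frozenset(sources)]] += 1
    return VennPartition(**counts)


@dataclass(frozen=True)
class CoverageReport:
    """Coverage percentages derived from a VennPartition, 1 d.p. half-up."""

    population: int
    union: int
    no_evidence: int
    union_prevalence_pct: float
    no_evidence_pct: float
    source_prevalence_pct: dict[str, float]  # of the population
    source_coverage_pct: dict[str, float]  # of the union
    codes_complement_pct: float  # union share NOT covered by diagnosis codes
    address_only_pct: float
    notes_only_pct: float
    address_and_notes_not_codes_pct: float
    single_source_pct: float

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "union": self.union,
            "no_evidence": self.no_evidence,
            "union_prevalence_pct": self.union_prevalence_pct,
            "no_evidence_pct": self.no_evidence_pct,
            "source_prevalence_pct": dict(self.source_prevalence_pct),
            "source_coverage_pct": dict(self.source_coverage_pct),
            "codes_complement_pct": self.codes_complement_pct,
            "address_only_pct": self.address_only_pct,
            "notes_only_pct": self.notes_only_pct,
            "address_and_notes_not_codes_pct": self.address_and_notes_not_codes_pct,
            "single_source_pct": self.single_source_pct,
        }


def coverage_summary(partition: VennPartition, population_size: int) -> CoverageReport:
    """Coverage report for one partition within a population.

    The diagnosis-code complement of the union splits into address-only,
    notes-only, and address-and-notes-without-codes shares.
    """
    union = partition.union
    if union > population_size:
        raise ValueError("union larger than population")
    totals = partition.totals()
    return CoverageReport(
        population=population_size,
        union=union,
        no_evidence=population_size - union,
        union_prevalence_pct=pct(union, population_size),
        no_evidence_pct=pct(population_size - union, population_size),
        source_prevalence_pct={s: pct(totals[s], population_size) for s in SOURCES},
        source_coverage_pct={s: pct(totals[s], union) for s in SOURCES},
        codes_complement_pct=pct(union - totals["diagnosis"], union),
        address_only_pct=pct(partition.a_only, union),
        notes_only_pct=pct(partition.n_only, union),
        address_and_notes_not_codes_pct=pct(partition.an, union),
        single_source_pct=pct(partition.single_source, union),
    )


@dataclass(frozen=True)
class TractDelta:
    """Codes-only versus all-sources identification, aggregated to tracts."""

    n_tracts: int
    missed_tracts: int  # zero codes-only but positive all-sources
    missed_pct: float
    increased_tracts: int  # strictly larger count under all-sources
    increased_pct: float
    mean_increase: float  # over tracts with any all-sources patient
    max_increase: int
    table: pd.DataFrame = field(compare=False)

    def to_dict(self) -> dict:
        return {
            "n_tracts": self.n_tracts,
            "missed_tracts": self.missed_tracts,
            "missed_pct": self.missed_pct,
            "increased_tracts": self.increased_tracts,
            "increased_pct": self.increased_pct,
            "mean_increase": self.mean_increase,
            "max_increase": self.max_increase,
        }


def tract_compare(
    patient_tracts: dict[str, str], source_sets: dict[str, frozenset[str]]
) -> TractDelta:
    """Per-tract identified counts under codes-only vs all-sources modes.

    Patients without a tract id aggregate into a sentinel "unknown" tract.
    The tract universe is every tract seen in ``patient_tracts``, so tracts
    with no identified patients under either mode still count toward the
    denominator.
    """
    tracts = sorted({str(t) if str(t).strip() else UNKNOWN_TRACT for t in patient_tracts.values()})
    codes_only = {t: 0 for t in tracts}
    all_sources = {t: 0 for t in tracts}
    for pid, sources in source_sets.items():
        if not sources:
            continue
        tract = str(patient_tracts.get(pid, "")).strip() or UNKNOWN_TRACT
        if tract not in codes_only:  # patient tract absent from the universe
            codes_only[tract] = 0
            all_sources[tract] = 0
            tracts.append(tract)
        all_sources[tract] += 1
        if "diagnosis" in sources:
            codes_only[tract] += 1
    rows = []
    for tract in tracts:
        rows.append(
            {
                "tract": tract,
                "codes_only": codes_only[tract],
                "all_sources": all_sources[tract],
                "increase": all_sources[tract] - codes_only[tract],
            }
        )
    table = pd.DataFrame(rows, columns=["tract", "codes_only", "all_sources", "increase"])
    missed = int(((table["codes_only"] == 0) & (table["all_sources"] > 0)).sum())
    increased = int((table["increase"] > 0).sum())
    touched = table[table["all_sources"] > 0]
    mean_increase = float(touched["increase"].mean()) if len(touched) else 0.0
    max_increase = int(table["increase"].max()) if len(table) else 0
    n_tracts = len(table)
    return TractDelta(
        n_tracts=n_tracts,
        missed_tracts=missed,
        missed_pct=pct(missed, n_tracts),
        increased_tracts=increased,
        increased_pct=pct(increased, n_tracts),
        mean_increase=mean_increase,
        max_increase=max_increase,
        table=table,
    )


def subgroup_coverage(
    union_ids: set[str], subgroup_ids: set[str], diagnosis_ids: set[str]
) -> dict:
    """Coverage of a patient subgroup (e.g. poisoning episodes) by diagnosis
    codes, within the identified union."""
    in_union = subgroup_ids & union_ids
    coded = in_union & diagnosis_ids
    return {
        "subgroup_total": len(subgroup_ids),
        "subgroup_in_union": len(in_union),
        "subgroup_in_union_pct": pct(len(in_union), len(subgroup_ids)),
        "coded_in_subgroup": len(coded),
        "diagnosis_coverage_pct": pct(len(coded), len(in_union)),
    }
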