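"""Seeded synthetic EHR generator with planted housing-instability truth.

The generator emulates the statistical shape the analysis assumes: an SUD
cohort mix with cohort-dependent demographics, a configurable housing
instability prevalence, per-source documentation sensitivities, false
documentation noise among stable patients, and note text containing
affirmed / negated / historical / third-party housing mentions plus
shelter-by-name mentions drawn from the community-resource directory.

Everything is driven by one ``numpy`` generator, so identical (config, seed)
produces byte-identical serialized output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from housinglens.records import (
    AddressRecord,
    ClinicalNote,
    Encounter,
    GroundTruth,
    PatientRecord,
)

SOURCES = ("diagnosis", "address", "note")
COHORTS = ("stimulant", "opioid", "both")

_BASE_DATE = date(2017, 1, 1)
_N_DAYS = 1611  # through 2021-05-31

# cohort-dependent demographic weights (qualitative Table-1-like structure:
# more males and Black patients in the stimulant cohort than the opioid one)
_SEX_MALE = {"stimulant": 0.597, "opioid": 0.472, "both": 0.55}
_RACE_P = {
    "stimulant": (0.78, 0.19, 0.03),
    "opioid": (0.92, 0.05, 0.03),
    "both": (0.85, 0.12, 0.03),
}
_RACES = ("White", "Black", "Other")
_AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65+")
_AGE_P = {
    "stimulant": (0.14, 0.32, 0.26, 0.16, 0.09, 0.03),
    "opioid": (0.07, 0.26, 0.25, 0.19, 0.15, 0.08),
    "both": (0.10, 0.33, 0.28, 0.17, 0.09, 0.03),
}

_STIM_F = ("F14.10", "F14.20", "F15.10", "F15.20")
_STIM_T = ("T40.5X1A", "T43.621A")
_OPI_F = ("F11.10", "F11.20", "F11.90")
_OPI_T = ("T40.2X1A", "T40.1X1A", "T40.4X1A", "T40.601A")
_Z59 = ("Z59.0", "Z59.00", "Z59.01", "Z59.1", "Z59.811")

_STREETS = ("Maple", "Oak", "Walnut", "Cedar", "Rose", "High", "Short", "Mill", "Vine", "Broadway")
_SUFFIXES = ("St", "Ave", "Rd", "Dr", "Ln", "Ct")


class TemplateError(KeyError):
    """A mention label without any template in the bank."""


@dataclass
class TemplateBank:
    """Sentence templates per mention label; shelter templates carry a
    ``{name}`` slot filled from the resource directory."""

    templates: dict[str, list[str]]
    resource_names: list[str]
    oov_phrases: list[str]

    def pick(self, label: str, rng: np.random.Generator) -> str:
        if label not in self.templates or not self.templates[label]:
            raise TemplateError(label)
        options = self.templates[label]
        template = options[int(rng.integers(len(options)))]
        if "{name}" in template:
            if not self.resource_names:
                raise TemplateError("shelter_name (no resources available)")
            name = self.resource_names[int(rng.integers(len(self.resource_names)))]
            template = template.format(name=name)
        return template


DEFAULT_TEMPLATES: dict[str, list[str]] = {
    "affirmed": [
        "Patient is homeless and sleeping outside.",
        "Patient reports unstable housing at this time.",
        "She is currently homeless.",
        "Patient has been living on the streets.",
        "Pt with chronic homelessness documented on intake.",
    ],
    "negated": [
        "Asked if she was homeless and she denied.",
        "Patient denies being homeless.",
        "No evidence of unstable housing.",
        "Patient is not homeless at this time.",
    ],
    "historical": [
        "History of homelessness several years ago.",
        "Patient was previously homeless.",
        "Years ago the patient experienced homelessness.",
    ],
    "third_party": [
        "Found a homeless person sleeping in her bathroom.",
        "Her boyfriend is homeless.",
        "Family member is currently homeless and staying with patient.",
    ],
    "shelter_name": [
        "Discharged to {name}.",
        "Lives at {name}.",
        "Transported from {name}.",
        "Social worker gave patient information about {name}.",
    ],
    "none": [
        "Vital signs stable.",
        "Patient tolerated the procedure well.",
        "Follow up in two weeks.",
        "Medication list reviewed and reconciled.",
        "No acute distress noted on exam.",
        "Labs ordered and pending.",
        "Patient reports mild headache this morning.",
        "Continue current medications.",
        "Discussed diet and exercise.",
        "Wound healing well without erythema.",
    ],
}

DEFAULT_OOV_PHRASES = [
    "Patient reports couch surfing with friends.",
    "He has been sleeping rough near the underpass.",
    "Patient is living out of a car this month.",
    "Currently doubling up with relatives.",
]


def default_template_bank() -> TemplateBank:
    frame = load_resource_frame()
    return TemplateBank(
        templates={k: list(v) for k, v in DEFAULT_TEMPLATES.items()},
        resource_names=list(frame["name"]),
        oov_phrases=list(DEFAULT_OOV_PHRASES),
    )


def load_resource_frame() -> pd.DataFrame:
    """Raw community-resource directory rows (needed for address planting)."""
    with resources.as_file(
        resources.files("housinglens.data").joinpath("resources.csv")
    ) as path:
        return pd.read_csv(path, dtype=str).fillna("")


@dataclass
class GenConfig:
    """Generator configuration; every random element flows from ``seed``."""

    n_patients: int
    seed: int
    cohort_mix: dict[str, float] = field(
        default_factory=lambda: {"stimulant": 0.45, "opioid": 0.40, "both": 0.15}
    )
    housing_prevalence: float = 0.292
    sensitivity: dict[str, float] = field(
        default_factory=lambda: {"diagnosis": 0.6, "address": 0.17, "note": 0.7}
    )
    specificity_noise: dict[str, float] = field(
        default_factory=lambda: {"diagnosis": 0.0, "address": 0.0, "note": 0.0}
    )
    negation_rate: float = 0.10
    history_rate: float = 0.10
    third_party_rate: float = 0.05
    generic_address_rate: float = 0.08
    oov_mention_rate: float = 0.05
    poisoning_rate: float = 0.20
    n_tracts: int = 30
    notes_mean: float = 3.0
    notes_dispersion: float = 1.0
    notes_cap: int = 50
    source_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be positive")
        if set(self.cohort_mix) != set(COHORTS):
            raise ValueError(f"cohort_mix must have keys {COHORTS}")
        total = sum(self.cohort_mix.values())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError("cohort_mix must sum to 1")
        for name in ("sensitivity", "specificity_noise"):
            mapping = getattr(self, name)
            if set(mapping) != set(SOURCES):
                raise ValueError(f"{name} must have keys {SOURCES}")
            for value in mapping.values():
                _check_rate(name, value)
        for name in (
            "housing_prevalence",
            "negation_rate",
            "history_rate",
            "third_party_rate",
            "generic_address_rate",
            "oov_mention_rate",
            "poisoning_rate",
            "source_correlation",
        ):
            _check_rate(name, getattr(self, name))
        if self.notes_mean <= 0 or self.notes_dispersion <= 0 or self.notes_cap < 1:
            raise ValueError("invalid notes-per-patient distribution parameters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _check_rate(name: str, value: float) -> None:
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} value {value!r} outside [0, 1]")


@dataclass(frozen=True)
class NoteRender:
    text: str
    sentences: list[tuple[str, str]]  # (label, realized sentence), in order


def render_note(
    labels: list[str], templates: TemplateBank, rng: np.random.Generator
) -> NoteRender:
    """Realize one sentence per label and join them into note text."""
    realized = [(label, templates.pick(label, rng)) for label in labels]
    return NoteRender(text=" ".join(s for _, s in realized), sentences=realized)


def _rand_date(rng: np.random.Generator) -> str:
    return (_BASE_DATE + timedelta(days=int(rng.integers(_N_DAYS + 1)))).isoformat()


def _documented_sources(
    rng: np.random.Generator, sensitivity: dict[str, float], correlation: float
) -> set[str]:
    """Per-source documentation events; a Gaussian-copula shared-severity
    knob induces positive correlation while preserving the marginals."""
    if correlation <= 0.0:
        return {s for s in SOURCES if rng.random() < sensitivity[s]}
    shared = rng.standard_normal()
    out = set()
    for s in SOURCES:
        z = np.sqrt(correlation) * shared + np.sqrt(1.0 - correlation) * rng.standard_normal()
        if norm.cdf(z) < sensitivity[s]:
            out.add(s)
    return out


def generate_dataset(
    config: GenConfig,
    templates: TemplateBank | None = None,
) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Generate the full synthetic dataset with planted ground truth.

    Every patient carries at least one SUD-defining code for their cohort;
    truly-unstable patients receive documentation per source independently
    with probability ``sensitivity[source]``; stable patients receive false
    documentation per source with probability ``specificity_noise[source]``
    (address noise is realized only as a resource address, never a literal
    "HOMELESS" line).
    """
    rng = np.random.default_rng(config.seed)
    bank = templates if templates is not None else default_template_bank()
    resource_frame = load_resource_frame()
    cohort_p = [config.cohort_mix[c] for c in COHORTS]
    nb_p = config.notes_dispersion / (config.notes_dispersion + config.notes_mean)

    patients: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    enc_seq = 0
    note_seq = 0

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        cohort = COHORTS[int(rng.choice(len(COHORTS), p=cohort_p))]
        sex = "M" if rng.random() < _SEX_MALE[cohort] else "F"
        race = _RACES[int(rng.choice(len(_RACES), p=_RACE_P[cohort]))]
        age_band = _AGE_BANDS[int(rng.choice(len(_AGE_BANDS), p=_AGE_P[cohort]))]
        tract = str(int(rng.integers(1, config.n_tracts + 1)))

        unstable = bool(rng.random() < config.housing_prevalence)
        if unstable:
            documented = _documented_sources(
                rng, config.sensitivity, config.source_correlation
            )
            noise: set[str] = set()
        else:
            documented = set()
            noise = {s for s in SOURCES if rng.random() < config.specificity_noise[s]}
        realized = documented | noise

        truth = GroundTruth(
            patient_id=pid,
            housing_unstable=unstable,
            documented_via=set(documented),
            noise_sources=set(noise),
        )

        # --- encounters -------------------------------------------------
        encounters: list[Encounter] = []

        def add_encounter(code: str) -> None:
            nonlocal enc_seq
            encounters.append(
                Encounter(
                    encounter_id=f"E{enc_seq:07d}",
                    patient_id=pid,
                    date=_rand_date(rng),
                    code=code,
                )
            )
            enc_seq += 1

        poisoning = rng.random() < config.poisoning_rate
        if cohort in ("stimulant", "both"):
            pool = _STIM_T if poisoning else _STIM_F
            add_encounter(pool[int(rng.integers(len(pool)))])
        if cohort in ("opioid", "both"):
            pool = _OPI_T if poisoning else _OPI_F
            add_encounter(pool[int(rng.integers(len(pool)))])
        for _ in range(int(rng.integers(0, 3))):  # extra cohort-consistent codes
            pool = _STIM_F if cohort == "stimulant" else _OPI_F if cohort == "opioid" else _STIM_F + _OPI_F
            add_encounter(pool[int(rng.integers(len(pool)))])
        if "diagnosis" in realized:
            add_encounter(_Z59[int(rng.integers(len(_Z59)))])

        # --- address ----------------------------------------------------
        addresses: list[AddressRecord] = []
        if "address" in realized:
            # noise is realized only as a resource address; true documentation
            # is a resource address most of the time, else a literal line
            use_literal = "address" in documented and rng.random() < 0.15
            if use_literal:
                addresses.append(
                    AddressRecord(pid, "HOMELESS", "", "Lexington", "KY", "40508", _rand_date(rng))
                )
            else:
                row = resource_frame.iloc[int(rng.integers(len(resource_frame)))]
                addresses.append(
                    AddressRecord(pid, row.line1, "", row.city, row.state, row.zip, _rand_date(rng))
                )
        elif rng.random() < config.generic_address_rate:
            addresses.append(
                AddressRecord(pid, "", "", "Lexington", "KY", "", _rand_date(rng))
            )
        else:
            line1 = (
                f"{int(rng.integers(100, 2500))} "
                f"{_STREETS[int(rng.integers(len(_STREETS)))]} "
                f"{_SUFFIXES[int(rng.integers(len(_SUFFIXES)))]}"
            )
            zip5 = f"405{int(rng.integers(0, 30)):02d}"
            addresses.append(
                AddressRecord(pid, line1, "", "Lexington", "KY", zip5, _rand_date(rng))
            )

        # --- notes ------------------------------------------------------
        n_notes = int(np.clip(rng.negative_binomial(config.notes_dispersion, nb_p), 1, config.notes_cap))
        note_labels: list[list[str]] = []
        for _ in range(n_notes):
            note_labels.append(["none"] * int(rng.integers(2, 5)))

        def plant(label: str) -> int:
            idx = int(rng.integers(n_notes))
            pos = int(rng.integers(len(note_labels[idx]) + 1))
            note_labels[idx].insert(pos, label)
            return idx

        if "note" in realized:
            n_mentions = 1 + int(rng.random() < 0.3)
            planted_docs = 0
            for m in range(n_mentions):
                u = rng.random()
                if u < config.negation_rate:
                    label = "negated"
                elif u < config.negation_rate + config.third_party_rate:
                    label = "third_party"
                elif u < config.negation_rate + config.third_party_rate + config.history_rate:
                    label = "historical"
                else:
                    label = "shelter_name" if rng.random() < 0.4 else "affirmed"
                if m == n_mentions - 1 and planted_docs == 0 and label in ("negated", "third_party"):
                    # guarantee the documentation event is actually documented
                    label = "affirmed"
                if label in ("affirmed", "historical", "shelter_name"):
                    planted_docs += 1
                plant(label)
        else:
            # distractor mentions that must NOT yield evidence
            if rng.random() < config.negation_rate:
                plant("negated")
            if rng.random() < config.third_party_rate:
                plant("third_party")

        oov_planted = rng.random() < config.oov_mention_rate
        oov_sentence = None
        oov_idx = None
        if oov_planted:
            oov_idx = int(rng.integers(n_notes))
            oov_sentence = bank.oov_phrases[int(rng.integers(len(bank.oov_phrases)))]
            truth.oov_planted = True

        notes: list[ClinicalNote] = []
        for idx, labels in enumerate(note_labels):
            render = render_note(labels, bank, rng)
            text = render.text
            if oov_idx == idx:
                text = f"{text} {oov_sentence}" if text else oov_sentence
            note = ClinicalNote(
                note_id=f"N{note_seq:07d}",
                patient_id=pid,
                date=_rand_date(rng),
                text=text,
            )
            note_seq += 1
            notes.append(note)
            for label, sentence in render.sentences:
                if label != "none":
                    truth.mention_labels.append((note.note_id, label, sentence))

        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                race=race,
                age_band=age_band,
                tract=tract,
                encounters=encounters,
                addresses=addresses,
                notes=notes,
            )
        )
        truths.append(truth)

    return patients, truths


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(
    patients: list[PatientRecord],
    truths: list[GroundTruth],
    config: GenConfig,
    outdir: str | Path,
) -> Path:
    """Write patients/encounters/addresses/truth as CSV, notes as JSONL, and
    echo the config as YAML.  Output is deterministic byte-for-byte."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "race": p.race,
                "age_band": p.age_band,
                "tract": p.tract,
            }
            for p in patients
        ],
        columns=["patient_id", "sex", "race", "age_band", "tract"],
    ).to_csv(out / "patients.csv", index=False)

    pd.DataFrame(
        [dataclasses.asdict(e) for p in patients for e in p.encounters],
        columns=["encounter_id", "patient_id", "date", "code"],
    ).to_csv(out / "encounters.csv", index=False)

    pd.DataFrame(
        [dataclasses.asdict(a) for p in patients for a in p.addresses],
        columns=["patient_id", "line1", "line2", "city", "state", "zip", "date"],
    ).to_csv(out / "addresses.csv", index=False)

    with open(out / "notes.jsonl", "w") as fh:
        for p in patients:
            for n in p.notes:
                fh.write(json.dumps(dataclasses.asdict(n), sort_keys=True) + "\n")

    pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "housing_unstable": int(t.housing_unstable),
                "documented_via": "|".join(sorted(t.documented_via)),
                "noise_sources": "|".join(sorted(t.noise_sources)),
                "oov_planted": int(t.oov_planted),
            }
            for t in truths
        ]
    ).to_csv(out / "truth.csv", index=False)

    pd.DataFrame(
        [
            {"note_id": nid, "patient_id": t.patient_id, "label": label, "sentence": sentence}
            for t in truths
            for nid, label, sentence in t.mention_labels
        ],
        columns=["note_id", "patient_id", "label", "sentence"],
    ).to_csv(out / "truth_mentions.csv", index=False)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"config": config.to_dict(), "config_hash": config.config_hash(), "seed": config.seed},
            fh,
            sort_keys=True,
        )
    return out


def load_dataset(indir: str | Path) -> tuple[list[PatientRecord], list[GroundTruth] | None]:
    """Load a dataset directory written by :func:`write_dataset` (or shaped
    like one); truth files are optional for real data."""
    indir = Path(indir)
    pframe = pd.read_csv(indir / "patients.csv", dtype=str).fillna("")
    eframe = pd.read_csv(indir / "encounters.csv", dtype=str).fillna("")
    aframe = pd.read_csv(indir / "addresses.csv", dtype=str).fillna("")

    enc_by_pid: dict[str, list[Encounter]] = {}
    for row in eframe.itertuples(index=False):
        enc_by_pid.setdefault(row.patient_id, []).append(
            Encounter(row.encounter_id, row.patient_id, row.date, row.code)
        )
    addr_by_pid: dict[str, list[AddressRecord]] = {}
    for row in aframe.itertuples(index=False):
        addr_by_pid.setdefault(row.patient_id, []).append(
            AddressRecord(row.patient_id, row.line1, row.line2, row.city, row.state, row.zip, row.date)
        )
    notes_by_pid: dict[str, list[ClinicalNote]] = {}
    with open(indir / "notes.jsonl") as fh:
        for line in fh:
            obj = json.loads(line)
            notes_by_pid.setdefault(obj["patient_id"], []).append(
                ClinicalNote(obj["note_id"], obj["patient_id"], obj["date"], obj["text"])
            )

    patients = [
        PatientRecord(
            patient_id=row.patient_id,
            sex=row.sex,
            race=row.race,
            age_band=row.age_band,
            tract=row.tract,
            encounters=enc_by_pid.get(row.patient_id, []),
            addresses=addr_by_pid.get(row.patient_id, []),
            notes=notes_by_pid.get(row.patient_id, []),
        )
        for row in pframe.itertuples(index=False)
    ]

    truths = None
    truth_path = indir / "truth.csv"
    if truth_path.exists():
        tframe = pd.read_csv(truth_path, dtype=str).fillna("")
        truths = [
            GroundTruth(
                patient_id=row.patient_id,
                housing_unstable=row.housing_unstable == "1",
                documented_via=set(filter(None, row.documented_via.split("|"))),
                noise_sources=set(filter(None, row.noise_sources.split("|"))),
                oov_planted=row.oov_planted == "1",
            )
            for row in tframe.itertuples(index=False)
        ]
        mention_path = indir / "truth_mentions.csv"
        if mention_path.exists() and truths:
            by_pid = {t.patient_id: t for t in truths}
            mframe = pd.read_csv(mention_path, dtype=str).fillna("")
            for row in mframe.itertuples(index=False):
                if row.patient_id in by_pid:
                    by_pid[row.patient_id].mention_labels.append(
                        (row.note_id, row.label, row.sentence)
                    )
    return patients, truths
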