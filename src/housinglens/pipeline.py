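"""End-to-end orchestration: generate or load data, run the three evidence
channels, fuse, test, and emit a report bundle.

Each stage logs one structured line with its input/output record counts so
the bundle's marginal totals can be reconciled against the patient count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from housinglens import codes, fusion, stats
from housinglens.addresses import ResourceDirectory, evaluate_address, most_recent_address
from housinglens.linker import (
    DEFAULT_ENTITY_PATTERNS,
    ConceptVocabulary,
    build_entity_index,
    detect_housing_concepts,
)
from housinglens.notes import Lexicon, ShelterMatcher, extract_note_evidence
from housinglens.records import EvidenceFlag, GroundTruth, Mention, PatientRecord, SOURCES
from housinglens.synthetic import GenConfig, generate_dataset, load_dataset, write_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one input mode plus channel toggles."""

    mode: str = "synthetic"  # synthetic | files
    gen: GenConfig | None = None
    data_dir: str | None = None
    out_dir: str = "housinglens_out"
    seed: int = 0
    lexicon_path: str | None = None
    directory_path: str | None = None
    vocabulary_path: str | None = None
    fuzzy_address: bool = True
    fuzzy_threshold: float = 0.92
    historical_evidence: bool = True
    third_party_evidence: bool = False
    residential_treatment_evidence: bool = True
    ner_enabled: bool = True
    adjudication_per_method: int = 100
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.data_dir:
            raise ValueError("files mode requires data_dir")
        if self.mode == "synthetic" and self.gen is None:
            self.gen = GenConfig(n_patients=500, seed=self.seed)

    def evidence_statuses(self) -> frozenset[str]:
        statuses = {"affirmed"}
        if self.historical_evidence:
            statuses.add("historical")
        if self.third_party_evidence:
            statuses.add("third_party")
        return frozenset(statuses)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("gen", None)
        config = cls(**raw)
        if gen is not None:
            config.gen = GenConfig(**gen)
        return config


@dataclass
class DetectionResult:
    """Per-channel outputs before fusion."""

    flags: list[EvidenceFlag]
    mentions: list[tuple[str, Mention]]  # (patient_id, mention)
    sud_type: dict[str, str]
    poisoning: dict[str, bool]
    generic_address: dict[str, bool]
    recognized_unlinked: int = 0
    literal_homeless_patients: set[str] = field(default_factory=set)
    resource_address_patients: set[str] = field(default_factory=set)


def detect_all(
    patients: list[PatientRecord],
    lexicon: Lexicon,
    directory: ResourceDirectory,
    vocab: ConceptVocabulary | None,
    *,
    fuzzy: bool = True,
    fuzzy_threshold: float = 0.92,
    include_residential_treatment: bool = True,
    evidence_statuses: frozenset[str] = frozenset({"affirmed", "historical"}),
    ner_enabled: bool = True,
) -> DetectionResult:
    """Run the diagnosis, address, and note channels over every patient."""
    result = DetectionResult(
        flags=[], mentions=[], sud_type={}, poisoning={}, generic_address={}
    )
    shelter_matcher = ShelterMatcher.build(directory, lexicon)
    entity_index = (
        build_entity_index(vocab, DEFAULT_ENTITY_PATTERNS)
        if ner_enabled and vocab is not None
        else None
    )
    for patient in patients:
        pid = patient.patient_id
        result.sud_type[pid] = codes.classify_sud(patient.encounters)
        result.poisoning[pid] = codes.detect_poisoning(patient.encounters)

        flag = codes.detect_housing_code(patient.encounters)
        if flag is not None:
            result.flags.append(flag)

        recent = most_recent_address(patient.addresses)
        generic = False
        if recent is not None:
            addr_flag, generic = evaluate_address(
                recent,
                directory,
                fuzzy=fuzzy,
                threshold=fuzzy_threshold,
                include_residential_treatment=include_residential_treatment,
            )
            if addr_flag is not None:
                result.flags.append(addr_flag)
                if addr_flag.method == "literal_homeless":
                    result.literal_homeless_patients.add(pid)
                else:
                    result.resource_address_patients.add(pid)
        result.generic_address[pid] = generic

        for note in patient.notes:
            mentions, note_flags = extract_note_evidence(
                note,
                lexicon,
                patient_id=pid,
                evidence_statuses=evidence_statuses,
                shelter_matcher=shelter_matcher,
            )
            result.mentions.extend((pid, m) for m in mentions)
            result.flags.extend(note_flags)
            if ner_enabled and vocab is not None:
                ner_flag, matches = detect_housing_concepts(
                    note,
                    vocab,
                    lexicon,
                    patient_id=pid,
                    entity_patterns=DEFAULT_ENTITY_PATTERNS,
                    evidence_statuses=evidence_statuses,
                    entity_index=entity_index,
                )
                result.recognized_unlinked += sum(
                    1 for m in matches if m.link_outcome == "recognized_unlinked"
                )
                if ner_flag is not None:
                    result.flags.append(ner_flag)
                    result.mentions.append(
                        (
                            pid,
                            Mention(
                                note_id=note.note_id,
                                method="ner",
                                surface=note.text[
                                    int(ner_flag.provenance.split(":")[1].split("-")[0]):
                                    int(ner_flag.provenance.split("-")[1])
                                ],
                                start=int(ner_flag.provenance.split(":")[1].split("-")[0]),
                                end=int(ner_flag.provenance.split("-")[1]),
                                sentence_index=0,
                            ),
                        )
                    )
    log.info(
        "detect: %d patients -> %d flags, %d mentions",
        len(patients),
        len(result.flags),
        len(result.mentions),
    )
    return result


def evaluate_against_truth(
    source_sets: dict[str, frozenset[str]],
    flags: list[EvidenceFlag],
    truths: list[GroundTruth],
) -> dict:
    """Per-source and per-method precision/recall/F1 against planted labels."""
    if truths is None:
        raise ValueError("truth evaluation requires synthetic mode")
    truth_by_pid = {t.patient_id: t for t in truths}

    def prf(tp: int, fp: int, fn: int) -> dict:
        precision = tp / (tp + fp) if (tp + fp) else float("nan")
        recall = tp / (tp + fn) if (tp + fn) else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall)
            if (tp + fp) and (tp + fn) and (precision + recall) > 0
            else float("nan")
        )
        return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "fp": fp, "fn": fn}

    report: dict = {"per_source": {}, "per_method": {}}
    for source in SOURCES:
        tp = fp = fn = 0
        for pid, truth in truth_by_pid.items():
            predicted = source in source_sets.get(pid, frozenset())
            documented = truth.housing_unstable and source in truth.documented_via
            if predicted and truth.housing_unstable:
                tp += 1
            elif predicted:
                fp += 1
            elif documented:
                fn += 1
        report["per_source"][source] = prf(tp, fp, fn)

    by_method: dict[str, set[str]] = {}
    for flag in flags:
        by_method.setdefault(flag.method, set()).add(flag.patient_id)
    for method, pids in sorted(by_method.items()):
        tp = sum(1 for pid in pids if truth_by_pid[pid].housing_unstable)
        report["per_method"][method] = {
            "patients": len(pids),
            "precision": tp / len(pids) if pids else float("nan"),
        }

    documentable = [t for t in truth_by_pid.values() if t.housing_unstable and t.documented_via]
    detected = sum(1 for t in documentable if source_sets.get(t.patient_id))
    report["union_recall"] = detected / len(documentable) if documentable else float("nan")
    predicted_any = [pid for pid, s in source_sets.items() if s]
    if predicted_any:
        report["union_precision"] = sum(
            1 for pid in predicted_any if truth_by_pid[pid].housing_unstable
        ) / len(predicted_any)
    else:
        report["union_precision"] = float("nan")
    return report


def _crosstab(rows: dict[str, str], cols: dict[str, str], pids: list[str]) -> pd.DataFrame:
    frame = pd.DataFrame({"row": [rows[p] for p in pids], "col": [cols[p] for p in pids]})
    return pd.crosstab(frame["row"], frame["col"])


def _safe_chi(table: pd.DataFrame) -> dict:
    try:
        res = stats.chi_squared(table.to_numpy())
        return {"statistic": res.statistic, "df": res.df, "p": res.p_value}
    except ValueError as exc:
        return {"error": str(exc)}


def _safe_fisher(table: pd.DataFrame, seed: int) -> dict:
    arr = table.to_numpy()
    try:
        p = stats.fisher_exact(arr, guard=200_000)
        return {"p": p, "method": "exact"}
    except stats.CapacityError:
        p = stats.fisher_exact(arr, monte_carlo=True, n_replicates=20_000, seed=seed)
        return {"p": p, "method": "monte_carlo", "replicates": 20_000, "seed": seed}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Returns the bundle as a dict (also serialized to ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("housinglens")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    if config.mode == "synthetic":
        patients, truths = generate_dataset(config.gen)
        write_dataset(patients, truths, config.gen, out / "dataset")
        config_hash = config.gen.config_hash()
    else:
        patients, truths = load_dataset(config.data_dir)
        config_hash = "files"
    log.info("input: %d patients", len(patients))

    lexicon = (
        Lexicon.from_yaml(config.lexicon_path) if config.lexicon_path else Lexicon.default()
    )
    directory = (
        ResourceDirectory.from_csv(config.directory_path)
        if config.directory_path
        else ResourceDirectory.from_csv(_default_directory_path())
    )
    vocab = (
        ConceptVocabulary.from_tsv(config.vocabulary_path)
        if config.vocabulary_path
        else ConceptVocabulary.default()
    )

    detection = detect_all(
        patients,
        lexicon,
        directory,
        vocab,
        fuzzy=config.fuzzy_address,
        fuzzy_threshold=config.fuzzy_threshold,
        include_residential_treatment=config.residential_treatment_evidence,
        evidence_statuses=config.evidence_statuses(),
        ner_enabled=config.ner_enabled,
    )

    patient_ids = [p.patient_id for p in patients]
    source_sets = fusion.fuse(detection.flags, patient_ids)
    partition = fusion.venn(source_sets)
    coverage = fusion.coverage_summary(partition, len(patients))
    tracts = fusion.tract_compare({p.patient_id: p.tract for p in patients}, source_sets)
    assert partition.union + coverage.no_evidence == len(patients)
    log.info(
        "fuse: union=%d no_evidence=%d (reconciles to %d patients)",
        partition.union,
        coverage.no_evidence,
        len(patients),
    )

    # ---- result tables -------------------------------------------------
    sud = detection.sud_type
    demo_tables = {}
    demo_fields = {
        "sex": {p.patient_id: p.sex for p in patients},
        "race": {p.patient_id: p.race for p in patients},
        "age_band": {p.patient_id: p.age_band for p in patients},
    }
    for name, mapping in demo_fields.items():
        table = _crosstab(mapping, sud, patient_ids)
        demo_tables[name] = {"table": table, "chi_squared": _safe_chi(table)}

    # housing evidence by source x SUD type
    rows = []
    for sud_type in sorted(set(sud.values())):
        pids = [pid for pid in patient_ids if sud[pid] == sud_type]
        entry = {"sud_type": sud_type, "n": len(pids)}
        for source in SOURCES:
            entry[source] = sum(1 for pid in pids if source in source_sets[pid])
        entry["any"] = sum(1 for pid in pids if source_sets[pid])
        entry["none"] = len(pids) - entry["any"]
        rows.append(entry)
    table2 = pd.DataFrame(rows)
    assert int(table2["n"].sum()) == len(patients)
    source_by_sud = table2.set_index("sud_type")[list(SOURCES)]
    table2_test = _safe_fisher(source_by_sud, config.seed)

    # note methods x SUD type
    method_sets: dict[str, set[str]] = {}
    for flag in detection.flags:
        if flag.source == "note":
            method_sets.setdefault(flag.method, set()).add(flag.patient_id)
    rows = []
    for method in ("keyword", "shelter_name", "ner"):
        pids = method_sets.get(method, set())
        entry = {"method": method, "patients": len(pids)}
        for sud_type in sorted(set(sud.values())):
            entry[sud_type] = sum(1 for pid in pids if sud[pid] == sud_type)
        rows.append(entry)
    table3 = pd.DataFrame(rows)
    table3_matrix = table3.set_index("method").drop(columns=["patients"])
    table3_test = (
        _safe_fisher(table3_matrix, config.seed)
        if int(table3_matrix.to_numpy().sum()) > 0
        else {"error": "no note evidence"}
    )

    # demographics by identifying source (Table-4 shape)
    table4 = {}
    for name, mapping in {**demo_fields, "poisoning": {
        pid: str(detection.poisoning[pid]) for pid in patient_ids
    }}.items():
        rows = []
        for source in SOURCES:
            pids = [pid for pid in patient_ids if source in source_sets[pid]]
            counts = pd.Series([mapping[pid] for pid in pids]).value_counts().to_dict()
            rows.append({"source": source, "n": len(pids), **counts})
        frame = pd.DataFrame(rows).fillna(0)
        matrix = frame.set_index("source").drop(columns=["n"])
        table4[name] = {
            "table": frame,
            "chi_squared": _safe_chi(matrix) if matrix.to_numpy().sum() > 0 else {"error": "empty"},
        }

    # poisoning subgroup coverage
    union_ids = {pid for pid, s in source_sets.items() if s}
    diagnosis_ids = {pid for pid, s in source_sets.items() if "diagnosis" in s}
    poisoning_ids = {pid for pid in patient_ids if detection.poisoning[pid]}
    poisoning_summary = fusion.subgroup_coverage(union_ids, poisoning_ids, diagnosis_ids)

    # adjudication sheet + (synthetic mode) simulated concordance
    mention_frame = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "note_id": m.note_id,
                "method": m.method,
                "surface": m.surface,
                "start": m.start,
                "end": m.end,
                "status": m.status,
                "resource_id": m.resource_id or "",
            }
            for pid, m in detection.mentions
        ],
        columns=["patient_id", "note_id", "method", "surface", "start", "end", "status", "resource_id"],
    )
    note_texts = {n.note_id: n.text for p in patients for n in p.notes}
    sheet = stats.sample_adjudication(
        mention_frame, note_texts, config.adjudication_per_method, config.seed
    )
    concordance: dict = {"sample_size": len(sheet)}
    if truths is not None and len(sheet):
        ratings, kappa, unanimity = _simulate_adjudication(sheet, truths, mention_frame, config.seed)
        concordance.update(
            {"fleiss_kappa": kappa, "unanimity_pct": unanimity, "n_raters": 3}
        )
        ratings.to_csv(out / "adjudication_ratings.csv", index=False)

    bundle = {
        "config_hash": config_hash,
        "seed": config.seed,
        "n_patients": len(patients),
        "coverage": coverage.to_dict(),
        "venn": {**partition.regions(), "union": partition.union, **{f"total_{k}": v for k, v in partition.totals().items()}},
        "tract_delta": tracts.to_dict(),
        "address_channel": {
            "literal_homeless": len(detection.literal_homeless_patients),
            "resource_address": len(detection.resource_address_patients),
            "generic": sum(detection.generic_address.values()),
        },
        "ner_recognized_unlinked": detection.recognized_unlinked,
        "poisoning": poisoning_summary,
        "tests": {
            "demographics_by_sud": {k: v["chi_squared"] for k, v in demo_tables.items()},
            "source_by_sud_fisher": table2_test,
            "note_method_by_sud_fisher": table3_test,
            "demographics_by_source": {k: v["chi_squared"] for k, v in table4.items()},
        },
        "concordance": concordance,
    }
    if truths is not None:
        bundle["truth_evaluation"] = evaluate_against_truth(
            source_sets, detection.flags, truths
        )

    # ---- serialize the bundle -----------------------------------------
    for name, entry in demo_tables.items():
        entry["table"].to_csv(out / f"table1_{name}.csv")
    table2.to_csv(out / "table2_by_source.csv", index=False)
    table3.to_csv(out / "table3_note_methods.csv", index=False)
    for name, entry in table4.items():
        entry["table"].to_csv(out / f"table4_{name}.csv", index=False)
    tracts.table.to_csv(out / "tract_counts.csv", index=False)
    mention_frame.to_csv(out / "mentions.csv", index=False)
    pd.DataFrame(
        [dataclasses.asdict(f) for f in detection.flags],
        columns=["patient_id", "source", "method", "provenance"],
    ).to_csv(out / "flags.csv", index=False)
    sheet.to_csv(out / "adjudication_sheet.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return bundle


def _simulate_adjudication(
    sheet: pd.DataFrame,
    truths: list[GroundTruth],
    mention_frame: pd.DataFrame,
    seed: int,
    error_rate: float = 0.15,
) -> tuple[pd.DataFrame, float, float]:
    """Simulated three-rater review against planted labels.

    Raters independently mislabel with ``error_rate``; extraction is "correct"
    when the sampled note's patient is truly unstable.
    """
    rng = np.random.default_rng(seed + 1)
    truth_by_pid = {t.patient_id: t for t in truths}
    pid_by_note = dict(zip(mention_frame["note_id"], mention_frame["patient_id"]))
    rows = []
    counts = []
    for note_id in sheet["note_id"]:
        pid = pid_by_note.get(note_id)
        correct = bool(pid and truth_by_pid[pid].housing_unstable)
        votes = [
            (not correct) if rng.random() < error_rate else correct for _ in range(3)
        ]
        n_yes = sum(votes)
        counts.append([n_yes, 3 - n_yes])
        rows.append(
            {
                "note_id": note_id,
                **{f"rater_{i+1}": ("correct" if v else "incorrect") for i, v in enumerate(votes)},
            }
        )
    matrix = stats.RatingMatrix(np.array(counts))
    try:
        kappa = stats.fleiss_kappa(matrix)
    except stats.UndefinedKappaError:
        kappa = float("nan")
    return pd.DataFrame(rows), kappa, 100.0 * stats.unanimity_rate(matrix)


def _default_directory_path():
    from importlib import resources

    return resources.files("housinglens.data").joinpath("resources.csv")
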