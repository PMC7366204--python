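"""Deterministic synthetic EHR generator with a planted diabetes phenotype.

Emulates the two source feeds the packaged evaluation needs: ICD-9-coded
diagnoses and LOINC-coded timestamped numeric labs (serum glucose
2345-7, HbA1c 4548-4), shaped like MIMIC-III's ``diagnoses_icd`` and
``labevents`` staging tables. A configurable fraction of patients is
planted as diabetes cases; every case satisfies at least one of the
three cohort criteria by construction and every control satisfies none:

* a diabetes diagnosis code (ICD-9 250.x family);
* last two consecutive serum glucose values > 126 mg/dL;
* last HbA1c > 6.4 %.

Value draws are truncated so criterion membership is crisp: case HbA1c
finals fall in (6.5, 12.0] and controls in [4.0, 6.4]; case last-two
glucose in (126, 300] while controls end on a value ≤ 126. Thresholds
are the cohort definition's; the distribution shapes are the
generator's. ``fuzzy=True`` additionally plants boundary patients whose
final values sit exactly at 6.4 / 126 — still outside the cohort under
strict ``>`` — for predicate-boundary testing.

Everything is a pure function of the seed: timestamps live on an
integer-hour grid, values are quantised to one decimal, and output
ordering is fixed, so the same config yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import random
import sqlite3
import warnings
from datetime import date, datetime, timedelta

from pydantic import BaseModel, Field, model_validator

from .cdi import CdiDocument, write_cdi as _write_cdi_doc
from .facts import EncounterRecord, ObservationFact, PatientRecord, format_datetime
from .ontology import ConceptHierarchy
from .store import PatientStore

GLUCOSE_CODE = "LOINC:2345-7"
HBA1C_CODE = "LOINC:4548-4"

#: ICD-9 250.x diabetes mellitus family (case pool)
DIABETES_DX_CODES = [
    "ICD9:250.00",
    "ICD9:250.01",
    "ICD9:250.02",
    "ICD9:250.50",
    "ICD9:250.60",
]

#: common non-diabetes diagnoses (control pool; no 250.x)
CONTROL_DX_CODES = [
    "ICD9:401.9",
    "ICD9:414.01",
    "ICD9:428.0",
    "ICD9:272.4",
    "ICD9:530.81",
    "ICD9:486",
    "ICD9:584.9",
    "ICD9:599.0",
]


class SynthConfig(BaseModel):
    n_patients: int = Field(default=1000, ge=1)
    seed: int = 11
    phenotype_prevalence: float = Field(default=0.3, ge=0.0, le=1.0)
    glucose_count: tuple[int, int] = (3, 8)  # measurements per patient (min, max)
    hba1c_count: tuple[int, int] = (1, 4)
    diagnosis_count: tuple[int, int] = (1, 4)
    start_date: date = date(2008, 1, 1)
    end_date: date = date(2012, 12, 31)
    case_hba1c: tuple[float, float] = (6.5, 12.0)
    control_hba1c: tuple[float, float] = (4.0, 6.4)
    case_glucose: tuple[float, float] = (126.2, 300.0)
    control_glucose_last: tuple[float, float] = (60.0, 126.0)
    glucose_any: tuple[float, float] = (60.0, 300.0)
    hba1c_any: tuple[float, float] = (4.0, 12.0)
    fuzzy: bool = False  # plant exact-boundary values (6.4 / 126.0)
    fuzzy_fraction: float = Field(default=0.25, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.end_date <= self.start_date:
            raise ValueError("end_date must follow start_date")
        for name in ("glucose_count", "hba1c_count", "diagnosis_count"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} range out of order")
        return self


@dataclasses.dataclass
class GroundTruth:
    """Planted per-criterion membership; the phenotype is their union."""

    cases: set[str]
    diagnosis_criterion: set[str]
    glucose_criterion: set[str]
    hba1c_criterion: set[str]

    @property
    def phenotype(self) -> set[str]:
        return self.diagnosis_criterion | self.glucose_criterion | self.hba1c_criterion

    def to_dict(self) -> dict:
        return {
            "cases": sorted(self.cases),
            "diagnosis_criterion": sorted(self.diagnosis_criterion),
            "glucose_criterion": sorted(self.glucose_criterion),
            "hba1c_criterion": sorted(self.hba1c_criterion),
        }


@dataclasses.dataclass
class SynthDataset:
    config: SynthConfig
    patients: list[PatientRecord]
    encounters: list[EncounterRecord]
    facts: list[ObservationFact]
    ground_truth: GroundTruth


def _q(value: float) -> float:
    return round(value, 1)


def generate(config: SynthConfig) -> SynthDataset:
    """Generate a dataset fully determined by ``config.seed``."""
    rng = random.Random(config.seed)
    n = config.n_patients
    span_hours = (config.end_date - config.start_date).days * 24
    t0 = datetime(config.start_date.year, config.start_date.month, config.start_date.day)

    n_cases = round(n * config.phenotype_prevalence)
    if config.phenotype_prevalence > 0 and n_cases == 0:
        warnings.warn(
            "prevalence * n_patients < 1; forcing a single case patient",
            stacklevel=2,
        )
        n_cases = 1
    case_indices = set(rng.sample(range(n), n_cases)) if n_cases else set()

    patients: list[PatientRecord] = []
    encounters: list[EncounterRecord] = []
    facts: list[ObservationFact] = []
    truth = GroundTruth(set(), set(), set(), set())

    for i in range(n):
        pid = f"P{i:05d}"
        birth = date(1930 + rng.randrange(70), 1 + rng.randrange(12), 1 + rng.randrange(28))
        patients.append(PatientRecord(pid, birth_date=birth, sex=rng.choice("FM")))
        enc_id = f"E{i:05d}"
        encounters.append(
            EncounterRecord(enc_id, pid, start_datetime=t0, end_datetime=None)
        )

        is_case = i in case_indices
        if is_case:
            truth.cases.add(pid)
            bits = rng.randint(1, 7)  # nonempty subset of the three criteria
            has_dx, has_glu, has_hba = bool(bits & 1), bool(bits & 2), bool(bits & 4)
        else:
            has_dx = has_glu = has_hba = False

        # -- diagnoses ------------------------------------------------------
        n_dx = rng.randint(*config.diagnosis_count)
        dx_codes = [rng.choice(CONTROL_DX_CODES) for _ in range(n_dx)]
        if has_dx:
            dx_codes.append(rng.choice(DIABETES_DX_CODES))
            truth.diagnosis_criterion.add(pid)
        dx_times = sorted(rng.sample(range(span_hours), len(dx_codes)))
        for code, hours in zip(dx_codes, dx_times):
            facts.append(
                ObservationFact(
                    patient_id=pid,
                    encounter_id=enc_id,
                    concept_code=code,
                    start_datetime=t0 + timedelta(hours=hours),
                    value_kind="flag",
                )
            )

        # -- serum glucose series ------------------------------------------
        n_glu = rng.randint(*config.glucose_count)
        if has_glu:
            n_glu = max(n_glu, 2)
        values = [_q(rng.uniform(*config.glucose_any)) for _ in range(n_glu)]
        if has_glu:
            values[-2:] = [_q(rng.uniform(*config.case_glucose)) for _ in range(2)]
            truth.glucose_criterion.add(pid)
        elif n_glu:
            values[-1] = _q(rng.uniform(*config.control_glucose_last))
            if (
                config.fuzzy
                and n_glu >= 2
                and rng.random() < config.fuzzy_fraction
            ):
                values[-2:] = [126.0, 126.0]  # exactly at threshold: strict > excludes
        glu_times = sorted(rng.sample(range(span_hours), n_glu))
        for value, hours in zip(values, glu_times):
            facts.append(
                ObservationFact(
                    patient_id=pid,
                    encounter_id=enc_id,
                    concept_code=GLUCOSE_CODE,
                    start_datetime=t0 + timedelta(hours=hours),
                    value_kind="numeric",
                    numeric_value=value,
                    unit="mg/dL",
                )
            )

        # -- HbA1c series ---------------------------------------------------
        n_hba = rng.randint(*config.hba1c_count)
        if has_hba:
            n_hba = max(n_hba, 1)
        values = [_q(rng.uniform(*config.hba1c_any)) for _ in range(n_hba)]
        if has_hba:
            values[-1] = _q(rng.uniform(*config.case_hba1c))
            truth.hba1c_criterion.add(pid)
        elif n_hba:
            values[-1] = _q(rng.uniform(*config.control_hba1c))
            if config.fuzzy and rng.random() < config.fuzzy_fraction:
                values[-1] = 6.4  # exactly at threshold: strict > excludes
        hba_times = sorted(rng.sample(range(span_hours), n_hba))
        for value, hours in zip(values, hba_times):
            facts.append(
                ObservationFact(
                    patient_id=pid,
                    encounter_id=enc_id,
                    concept_code=HBA1C_CODE,
                    start_datetime=t0 + timedelta(hours=hours),
                    value_kind="numeric",
                    numeric_value=value,
                    unit="%",
                )
            )

    return SynthDataset(
        config=config,
        patients=patients,
        encounters=encounters,
        facts=facts,
        ground_truth=truth,
    )


# -- concept hierarchies ----------------------------------------------------


def labs_hierarchy() -> ConceptHierarchy:
    """Small lab catalogue covering the generated LOINC codes."""
    h = ConceptHierarchy()
    h.add_node("Labs", name="Labs")
    h.add_node("Labs/Serum or Plasma", name="Serum or Plasma")
    h.add_node(
        "Labs/Serum or Plasma/Serum Glucose",
        code=GLUCOSE_CODE,
        name="Glucose [Mass/volume]",
    )
    h.add_node(
        "Labs/Serum or Plasma/HbA1c", code=HBA1C_CODE, name="Hemoglobin A1c"
    )
    return h


def diagnosis_hierarchy() -> ConceptHierarchy:
    """ICD-9 catalogue covering the generated case and control pools."""
    h = ConceptHierarchy()
    h.add_node("Diagnoses", name="Diagnoses")
    h.add_node("Diagnoses/Diabetes mellitus", name="Diabetes mellitus")
    for code in DIABETES_DX_CODES:
        bare = code.split(":", 1)[1]
        h.add_node(f"Diagnoses/Diabetes mellitus/{bare}", code=code, name=f"ICD-9 {bare}")
    h.add_node("Diagnoses/Other", name="Other")
    for code in CONTROL_DX_CODES:
        bare = code.split(":", 1)[1]
        h.add_node(f"Diagnoses/Other/{bare}", code=code, name=f"ICD-9 {bare}")
    return h


def write_labs_hierarchy_tsv(target) -> None:
    labs_hierarchy().write_tsv(target)


def write_diagnosis_hierarchy_tsv(target) -> None:
    diagnosis_hierarchy().write_tsv(target)


# -- ingestion-path writers -------------------------------------------------


def load_direct(dataset: SynthDataset, store: PatientStore, source_logic: str = "direct") -> int:
    """Reference ingestion path: insert the dataset straight into a store."""
    store.add_patients(dataset.patients)
    store.add_encounters(dataset.encounters)
    facts = [dataclasses.replace(f, source_logic=source_logic) for f in dataset.facts]
    return store.insert_facts(facts)


def write_cdi(dataset: SynthDataset, target) -> None:
    """Write the dataset as a single i2b2-cdi file (concepts then facts)."""
    concepts: list[tuple[str, str, str]] = []
    for h in (diagnosis_hierarchy(), labs_hierarchy()):
        for path in sorted(h.nodes):
            node = h.nodes[path]
            concepts.append((node.path, node.code, node.name))
    doc = CdiDocument(concepts=concepts, mappings=[], facts=list(dataset.facts))
    _write_cdi_doc(doc, target)


def write_fact_csv(dataset: SynthDataset, target: str) -> int:
    """Write the dataset through the store's CSV fact dialect."""
    store = PatientStore()
    try:
        load_direct(dataset, store, source_logic="")
        return store.export_csv(target)
    finally:
        store.close()


def write_source_tables(dataset: SynthDataset, path: str, append: bool = False) -> dict:
    """Stage the dataset as MIMIC-III-shaped relational tables.

    Creates ``diagnoses_icd(subject_id, hadm_id, icd9_code, charttime)``
    and ``labevents(subject_id, hadm_id, loinc_code, charttime, valuenum,
    valueuom)`` in a SQLite file, each with a monotone ``row_id`` suitable
    as a watermark field. Codes are stored bare (no ``ICD9:``/``LOINC:``
    namespace), as a source system would; the import Logics re-attach the
    namespace. Returns per-table row counts.
    """
    conn = sqlite3.connect(path)
    try:
        with conn:
            if not append:
                conn.execute("DROP TABLE IF EXISTS diagnoses_icd")
                conn.execute("DROP TABLE IF EXISTS labevents")
            conn.execute(
                "CREATE TABLE IF NOT EXISTS diagnoses_icd ("
                "row_id INTEGER PRIMARY KEY AUTOINCREMENT, subject_id TEXT, "
                "hadm_id TEXT, icd9_code TEXT, charttime TEXT)"
            )
            conn.execute(
                "CREATE TABLE IF NOT EXISTS labevents ("
                "row_id INTEGER PRIMARY KEY AUTOINCREMENT, subject_id TEXT, "
                "hadm_id TEXT, loinc_code TEXT, charttime TEXT, "
                "valuenum REAL, valueuom TEXT)"
            )
            n_dx = n_lab = 0
            for f in dataset.facts:
                system, bare = f.concept_code.split(":", 1)
                when = format_datetime(f.start_datetime)
                if system == "ICD9":
                    conn.execute(
                        "INSERT INTO diagnoses_icd (subject_id, hadm_id, icd9_code, "
                        "charttime) VALUES (?,?,?,?)",
                        (f.patient_id, f.encounter_id, bare, when),
                    )
                    n_dx += 1
                elif system == "LOINC":
                    conn.execute(
                        "INSERT INTO labevents (subject_id, hadm_id, loinc_code, "
                        "charttime, valuenum, valueuom) VALUES (?,?,?,?,?,?)",
                        (f.patient_id, f.encounter_id, bare, when, f.numeric_value, f.unit),
                    )
                    n_lab += 1
        return {"diagnoses_icd": n_dx, "labevents": n_lab}
    finally:
        conn.close()


def write_ground_truth_json(dataset: SynthDataset, target: str) -> None:
    with open(target, "w", encoding="utf-8") as fh:
        json.dump(dataset.ground_truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
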