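"""Packaged diabetes-cohort example: the Logic set and query.

This is the worked end-to-end configuration the engine ships with: two
SQL import Logics over MIMIC-III-shaped staging tables, two
concept-hierarchy Logics, four derived-concept Logics, and the
three-criterion cohort query

* any ICD-9 250.x diabetes diagnosis code, OR
* last two consecutive serum glucose > 126 mg/dL, OR
* last HbA1c > 6.4 %.

Thresholds are parameters — a stricter screen (e.g. HbA1c > 9.4) is the
same query with a different number.
"""

from __future__ import annotations

from .logics import Logic
from .query import CohortQuery, QueryNode
from .synth import GLUCOSE_CODE, HBA1C_CODE

DIAGNOSIS_IMPORT = "Diagnosis-import"
LABS_IMPORT = "Labs-import"
DIAGNOSIS_HIERARCHY = "Diagnosis-hierarchy"
LABS_HIERARCHY = "Labs-hierarchy"
DX_DIABETES = "Diagnosis-Diabetes"
LAST_HBA1C = "Last-HbA1c"
LAST_GLUCOSE = "Last-Glucose"
LAST_TWO_GLUCOSE = "Last-Two-Glucose-High"


def import_logics(staging_db: str, batch_count: int = 500) -> list[Logic]:
    """SQL import Logics over ``diagnoses_icd`` / ``labevents`` staging tables.

    Both are watermarked on the tables' monotone ``row_id``, so re-running
    on an unchanged source imports nothing and appended rows import
    incrementally.
    """
    return [
        Logic(
            name=DIAGNOSIS_IMPORT,
            logic_type="import",
            logic_path="Import/Diagnosis-import",
            modality="sql",
            spec={
                "source": staging_db,
                "extract_query": (
                    "SELECT row_id, subject_id, hadm_id, icd9_code, charttime "
                    "FROM diagnoses_icd ORDER BY row_id"
                ),
                "watermark_field": "row_id",
                "batch_count": batch_count,
                "mapping": {
                    "patient_id": "subject_id",
                    "encounter_id": "hadm_id",
                    "concept_code": {"column": "icd9_code", "prefix": "ICD9:"},
                    "start_datetime": "charttime",
                    "value_kind": {"const": "flag"},
                },
            },
        ),
        Logic(
            name=LABS_IMPORT,
            logic_type="import",
            logic_path="Import/Labs-import",
            modality="sql",
            spec={
                "source": staging_db,
                "extract_query": (
                    "SELECT row_id, subject_id, hadm_id, loinc_code, charttime, "
                    "valuenum, valueuom FROM labevents ORDER BY row_id"
                ),
                "watermark_field": "row_id",
                "batch_count": batch_count,
                "mapping": {
                    "patient_id": "subject_id",
                    "encounter_id": "hadm_id",
                    "concept_code": {"column": "loinc_code", "prefix": "LOINC:"},
                    "start_datetime": "charttime",
                    "value_kind": {"const": "numeric"},
                    "numeric_value": "valuenum",
                    "unit": "valueuom",
                },
            },
        ),
    ]


def hierarchy_logics(diagnosis_tsv: str, labs_tsv: str) -> list[Logic]:
    return [
        Logic(
            name=DIAGNOSIS_HIERARCHY,
            logic_type="concept_hierarchy",
            logic_path="Concept_Hierarchy/Diagnosis-hierarchy",
            modality="cdi_file",
            spec={"file": diagnosis_tsv},
        ),
        Logic(
            name=LABS_HIERARCHY,
            logic_type="concept_hierarchy",
            logic_path="Concept_Hierarchy/Labs-hierarchy",
            modality="cdi_file",
            spec={"file": labs_tsv},
        ),
    ]


def derived_logics(glucose_threshold: float = 126.0) -> list[Logic]:
    """The four derived concepts behind the diabetes criteria."""
    return [
        Logic(
            name=DX_DIABETES,
            logic_type="derived_concept",
            logic_path="Derived_Concept/Diagnosis-Diabetes",
            modality="sql",
            spec={
                "name": DX_DIABETES,
                "concept_path": "Derived/Diagnosis/Diabetes",
                "result_kind": "boolean",
                "operator": "any_code_present",
                "code_prefix": "ICD9:250",
            },
        ),
        Logic(
            name=LAST_HBA1C,
            logic_type="derived_concept",
            logic_path="Labs/BloodTest/Chemistry/HbA1c/Last-HbA1c",
            modality="sql",
            spec={
                "name": LAST_HBA1C,
                "concept_path": "Derived/Labs/Blood/Chemistry/HbA1c/LastHbA1c",
                "result_kind": "numeric",
                "operator": "last_value",
                "source": HBA1C_CODE,
            },
        ),
        Logic(
            name=LAST_GLUCOSE,
            logic_type="derived_concept",
            logic_path="Labs/BloodTest/Chemistry/Glucose/Last-Glucose",
            modality="sql",
            spec={
                "name": LAST_GLUCOSE,
                "concept_path": "Derived/Labs/Blood/Chemistry/Glucose/LastGlucose",
                "result_kind": "numeric",
                "operator": "last_value",
                "source": GLUCOSE_CODE,
            },
        ),
        Logic(
            name=LAST_TWO_GLUCOSE,
            logic_type="derived_concept",
            logic_path="Labs/BloodTest/Chemistry/Glucose/Last-Two-Glucose-High",
            modality="sql",
            spec={
                "name": LAST_TWO_GLUCOSE,
                "concept_path": "Derived/Labs/Blood/Chemistry/Glucose/LastTwoGlucoseHigh",
                "result_kind": "boolean",
                "operator": "last_n_consecutive_compare",
                "source": GLUCOSE_CODE,
                "n": 2,
                "comparator": ">",
                "threshold": glucose_threshold,
            },
        ),
    ]


def all_logics(
    staging_db: str,
    diagnosis_tsv: str,
    labs_tsv: str,
    batch_count: int = 500,
    glucose_threshold: float = 126.0,
) -> list[Logic]:
    """The full eight-Logic catalogue for the diabetes evaluation."""
    return (
        import_logics(staging_db, batch_count)
        + hierarchy_logics(diagnosis_tsv, labs_tsv)
        + derived_logics(glucose_threshold)
    )


def diabetes_query(hba1c_threshold: float = 6.4) -> CohortQuery:
    """Three-criterion diabetes cohort query (three sibling OR roots)."""
    return CohortQuery(
        name="diabetes-cohort",
        roots=[
            QueryNode(
                node_id="dx",
                label="Diagnoses code of diabetes",
                codes=[f"DERIVED:{DX_DIABETES}"],
                operator="exists",
            ),
            QueryNode(
                node_id="glucose",
                label="Last two consecutive serum glucose > 126",
                codes=[f"DERIVED:{LAST_TWO_GLUCOSE}"],
                operator="exists",
            ),
            QueryNode(
                node_id="hba1c",
                label=f"Last HbA1c > {hba1c_threshold:g}",
                codes=[f"DERIVED:{LAST_HBA1C}"],
                operator=">",
                threshold=hba1c_threshold,
            ),
        ],
    )
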