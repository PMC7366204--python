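"""Logic definitions: named, typed, cataloged pipeline components.

A Logic is one of four types — ``import`` (move facts from a source into
the store), ``concept_hierarchy`` (build the concept catalogue),
``code_map`` (attach local codes to standard ones), ``derived_concept``
(compute per-patient derived facts) — realised in one of three
modalities: ``sql`` (extract query against a relational staging source,
or the engine's built-in derived operators), ``cdi_file`` (flat-file
import carrying its own concept metadata, also used for TSV hierarchy
and mapping files), or ``script`` (registered plugin).

Definitions are plain pydantic models and round-trip through YAML
field-for-field.
"""

from __future__ import annotations

from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError

LogicType = Literal["import", "concept_hierarchy", "code_map", "derived_concept"]
Modality = Literal["sql", "cdi_file", "script"]

Comparator = Literal[">", "<", ">=", "<=", "≥", "≤"]


class SqlImportSpec(BaseModel):
    """SQL-modality import: extract rows from a staging database.

    ``mapping`` maps ObservationFact fields to source columns. Each entry
    is either a bare column name, ``{"column": col, "prefix": "ICD9:"}``
    (prepend a coding-system namespace), or ``{"const": value}``.
    ``watermark_field`` enables incremental loading: only rows whose
    watermark value is strictly greater than the stored high-water mark
    are imported, and the mark advances to the maximum seen.
    """

    source: str
    extract_query: str
    mapping: dict[str, Any]
    watermark_field: Optional[str] = None
    batch_count: int = Field(default=1000, ge=1)
    concept_mapping: Optional[str] = None  # path to a local/standard mapping TSV
    concept_mapping_direction: Literal["local_to_standard", "standard_to_local"] = (
        "local_to_standard"
    )
    algorithm: Optional[str] = None  # per-row transform plugin name

    @model_validator(mode="after")
    def _check_mapping(self):
        required = {"patient_id", "concept_code", "start_datetime"}
        missing = required - set(self.mapping)
        if missing:
            raise ValueError(f"mapping must cover {sorted(missing)}")
        return self


class CdiFileSpec(BaseModel):
    """i2b2-cdi flat-file import (facts plus embedded concept metadata)."""

    file: str


class TsvFileSpec(BaseModel):
    """Concept-hierarchy or code-map TSV file."""

    file: str
    separator: Literal["/", "\\"] = "/"


class ScriptSpec(BaseModel):
    """Plugin-backed import: the registered plugin yields ObservationFacts."""

    plugin: str


class DerivedConceptDef(BaseModel):
    """A computation over base (or other derived) facts.

    Built-in operators:

    ``last_value``
        per patient, copy the chronologically last numeric source fact
        (value and timestamp) as a derived numeric fact.
    ``last_n_consecutive_compare``
        flag patients whose final ``n`` source measurements *all* satisfy
        ``comparator threshold`` (e.g. last two serum glucose > 126).
    ``any_code_present``
        flag patients holding at least one fact whose code is in the
        expansion of ``path`` / ``codes`` / ``code_prefix``; timestamped
        at the earliest match.
    ``compare_derived``
        flag patients whose derived numeric ``source`` value satisfies
        ``comparator threshold``.
    ``script``
        registered plugin called once per patient with the sorted chart.
    """

    name: str
    concept_path: str
    result_kind: Literal["boolean", "numeric"]
    operator: Literal[
        "last_value",
        "last_n_consecutive_compare",
        "any_code_present",
        "compare_derived",
        "script",
    ]
    source: Optional[str] = None
    n: Optional[int] = Field(default=None, ge=1)
    comparator: Optional[Comparator] = None
    threshold: Optional[float] = None
    codes: Optional[list[str]] = None
    code_prefix: Optional[str] = None
    path: Optional[str] = None
    plugin: Optional[str] = None

    @property
    def output_code(self) -> str:
        return f"DERIVED:{self.name}"

    @model_validator(mode="after")
    def _check_operator_params(self):
        op = self.operator
        if op == "last_value":
            if not self.source:
                raise ValueError("last_value requires a source concept ref")
            if self.result_kind != "numeric":
                raise ValueError("last_value emits numeric facts")
        elif op == "last_n_consecutive_compare":
            if not (self.source and self.n and self.comparator and self.threshold is not None):
                raise ValueError(
                    "last_n_consecutive_compare requires source, n, comparator, threshold"
                )
            if self.result_kind != "boolean":
                raise ValueError("last_n_consecutive_compare emits flag facts")
        elif op == "any_code_present":
            if not (self.codes or self.code_prefix or self.path):
                raise ValueError("any_code_present requires codes, code_prefix or path")
            if self.result_kind != "boolean":
                raise ValueError("any_code_present emits flag facts")
        elif op == "compare_derived":
            if not (self.source and self.comparator and self.threshold is not None):
                raise ValueError("compare_derived requires source, comparator, threshold")
            if self.result_kind != "boolean":
                raise ValueError("compare_derived emits flag facts")
        elif op == "script":
            if not self.plugin:
                raise ValueError("script operator requires a plugin ref")
        return self

    def source_refs(self) -> list[str]:
        """Concept refs this definition reads (for dependency planning)."""
        refs = []
        if self.source:
            refs.append(self.source)
        if self.codes:
            refs.extend(self.codes)
        if self.path:
            refs.append(self.path)
        return refs


_SPEC_DISPATCH: dict[tuple[str, str], type[BaseModel]] = {
    ("import", "sql"): SqlImportSpec,
    ("import", "cdi_file"): CdiFileSpec,
    ("import", "script"): ScriptSpec,
    ("concept_hierarchy", "cdi_file"): TsvFileSpec,
    ("code_map", "cdi_file"): TsvFileSpec,
    ("derived_concept", "sql"): DerivedConceptDef,
    ("derived_concept", "script"): DerivedConceptDef,
}


class Logic(BaseModel):
    """A named, typed pipeline definition with a catalogue path."""

    name: str
    logic_type: LogicType
    logic_path: str
    modality: Modality
    spec: dict[str, Any] = Field(default_factory=dict)
    schedule: Optional[str] = None  # free-form tag; executed only via run_due()

    @field_validator("logic_path")
    @classmethod
    def _nonempty_path(cls, v: str) -> str:
        v = v.strip().strip("/")
        if not v:
            raise ValueError("logic_path must be non-empty")
        return v

    @model_validator(mode="after")
    def _check_combination(self):
        key = (self.logic_type, self.modality)
        if key not in _SPEC_DISPATCH:
            raise ValueError(
                f"invalid logic_type/modality combination {key}; "
                f"valid: {sorted(_SPEC_DISPATCH)}"
            )
        return self

    def typed_spec(self) -> BaseModel:
        """Parse ``spec`` with the model matching (logic_type, modality)."""
        model = _SPEC_DISPATCH[(self.logic_type, self.modality)]
        try:
            parsed = model.model_validate(self.spec)
        except Exception as exc:
            raise ConfigurationError(f"logic {self.name!r}: {exc}") from exc
        if self.logic_type == "derived_concept":
            is_script = parsed.operator == "script"
            if is_script != (self.modality == "script"):
                raise ConfigurationError(
                    f"logic {self.name!r}: operator {parsed.operator!r} requires "
                    f"modality {'script' if is_script else 'sql'}"
                )
        return parsed


def load_logics_yaml(source) -> list[Logic]:
    """Read one Logic or a list of Logics from a YAML file or string."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        try:
            with open(source, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(source)
    if data is None:
        return []
    if isinstance(data, dict):
        data = [data]
    return [Logic.model_validate(item) for item in data]


def dump_logic_yaml(logic: Logic) -> str:
    return yaml.safe_dump(logic.model_dump(exclude_none=True), sort_keys=False)
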