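"""Core star-schema record types: observation facts, patients, encounters.

An :class:`ObservationFact` is one coded clinical observation for a patient
at a point in time — the row type of the i2b2-style ``observation_fact``
table. Concept codes are namespaced as ``SYSTEM:code`` (``ICD9:250.00``,
``LOINC:2345-7``, ``DERIVED:LastHbA1c``) so multiple coding systems and
local codes coexist in one fact table without collision.

Timestamps are timezone-naive (source-local), matching typical EHR
extracts; they are normalised to whole-second ISO-8601 for storage so that
lexicographic and chronological order coincide.
"""

from __future__ import annotations

import dataclasses
from datetime import date, datetime

from .errors import FactValidationError

VALUE_KINDS = ("numeric", "text", "flag")

DT_FORMAT = "%Y-%m-%dT%H:%M:%S"


def parse_datetime(value: datetime | date | str) -> datetime:
    """Coerce a timestamp-ish value to a naive datetime.

    Accepts datetimes, dates and ISO-8601 strings. Timezone-aware values
    are rejected: the store is defined over source-local naive time.
    """
    if isinstance(value, datetime):
        dt = value
    elif isinstance(value, date):
        dt = datetime(value.year, value.month, value.day)
    elif isinstance(value, str):
        try:
            dt = datetime.fromisoformat(value.strip().replace(" ", "T", 1))
        except ValueError:
            raise FactValidationError(
                "start_datetime", f"unparseable timestamp {value!r}"
            ) from None
    else:
        raise FactValidationError(
            "start_datetime", f"expected datetime or ISO string, got {type(value).__name__}"
        )
    if dt.tzinfo is not None:
        raise FactValidationError("start_datetime", "timestamps must be timezone-naive")
    return dt


def format_datetime(dt: datetime) -> str:
    return dt.strftime(DT_FORMAT)


@dataclasses.dataclass
class ObservationFact:
    """One coded, optionally valued, timestamped observation for a patient.

    Exactly one value payload must match ``value_kind``: numeric facts
    carry ``numeric_value`` (plus an optional unit), text facts carry
    ``text_value``, and flag facts carry no payload at all.
    """

    patient_id: str
    concept_code: str
    start_datetime: datetime | str
    value_kind: str = "flag"
    numeric_value: float | None = None
    unit: str | None = None
    text_value: str | None = None
    encounter_id: str | None = None
    provider_id: str | None = None
    source_logic: str = ""

    def validate(self, row: int | None = None) -> "ObservationFact":
        """Check invariants, normalising the timestamp in place.

        Raises :class:`FactValidationError` naming the offending field.
        """
        if not str(self.patient_id):
            raise FactValidationError("patient_id", "must be non-empty", row)
        if not self.concept_code:
            raise FactValidationError("concept_code", "must be non-empty", row)
        if self.value_kind not in VALUE_KINDS:
            raise FactValidationError(
                "value_kind", f"{self.value_kind!r} not in {VALUE_KINDS}", row
            )
        try:
            self.start_datetime = parse_datetime(self.start_datetime)
        except FactValidationError as exc:
            raise FactValidationError("start_datetime", str(exc), row) from None
        if self.value_kind == "numeric":
            if self.numeric_value is None:
                raise FactValidationError(
                    "numeric_value", "required when value_kind=numeric", row
                )
            try:
                self.numeric_value = float(self.numeric_value)
            except (TypeError, ValueError):
                raise FactValidationError(
                    "numeric_value", f"not numeric: {self.numeric_value!r}", row
                ) from None
            if self.text_value is not None:
                raise FactValidationError(
                    "text_value", "must be absent when value_kind=numeric", row
                )
        elif self.value_kind == "text":
            if self.text_value is None:
                raise FactValidationError(
                    "text_value", "required when value_kind=text", row
                )
            if self.numeric_value is not None:
                raise FactValidationError(
                    "numeric_value", "must be absent when value_kind=text", row
                )
        else:  # flag
            if self.numeric_value is not None or self.text_value is not None:
                raise FactValidationError(
                    "numeric_value" if self.numeric_value is not None else "text_value",
                    "flag facts carry no value payload",
                    row,
                )
        return self

    def key(self, include_source: bool = False) -> tuple:
        """Identity tuple used to compare facts across ingestion paths.

        ``source_logic``/``provider_id`` are provenance, not content, so
        they are excluded unless requested.
        """
        dt = self.start_datetime
        base = (
            str(self.patient_id),
            self.encounter_id if self.encounter_id is None else str(self.encounter_id),
            self.concept_code,
            format_datetime(dt) if isinstance(dt, datetime) else str(dt),
            self.value_kind,
            self.numeric_value,
            self.unit,
            self.text_value,
        )
        if include_source:
            base = base + (self.provider_id, self.source_logic)
        return base


@dataclasses.dataclass
class PatientRecord:
    patient_id: str
    birth_date: date | None = None
    sex: str | None = None


@dataclasses.dataclass
class EncounterRecord:
    encounter_id: str
    patient_id: str
    start_datetime: datetime | str | None = None
    end_datetime: datetime | str | None = None
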