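"""i2b2-style star-schema patient store backed by an embedded SQLite file.

Table layout mirrors the i2b2 column roles under clearer names:

==================  =====================
i2b2 role           cohortforge column
==================  =====================
patient_num         patient_id
concept_cd          concept_code
start_date          start_datetime
nval_num            numeric_value
units_cd            unit
tval_char           text_value
provider_id         provider_id
sourcesystem_cd     source_logic
==================  =====================

Facts are append-only; ``fact_id`` is an AUTOINCREMENT key, so insertion
order is total and stable even across deletes (used as the tie-break for
equal timestamps). Per-Logic import watermarks live in the same database
so incremental loading state travels with the store file.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from datetime import datetime
from typing import Iterable, Sequence

from .errors import ConfigurationError, FactValidationError, NotFoundError
from .facts import (
    EncounterRecord,
    ObservationFact,
    PatientRecord,
    format_datetime,
    parse_datetime,
)

#: operators accepted by value predicates; unicode aliases normalised.
OPERATORS = {
    ">": ">",
    "<": "<",
    ">=": ">=",
    "≥": ">=",
    "<=": "<=",
    "≤": "<=",
    "=": "=",
    "==": "=",
    "exists": "exists",
}

CSV_HEADER = [
    "patient_id",
    "encounter_id",
    "concept_code",
    "start_datetime",
    "value_kind",
    "numeric_value",
    "unit",
    "text_value",
    "provider_id",
    "source_logic",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS patient_dimension (
    patient_id TEXT PRIMARY KEY,
    birth_date TEXT,
    sex TEXT
);
CREATE TABLE IF NOT EXISTS encounter_dimension (
    encounter_id TEXT PRIMARY KEY,
    patient_id TEXT NOT NULL,
    start_datetime TEXT,
    end_datetime TEXT
);
CREATE TABLE IF NOT EXISTS observation_fact (
    fact_id INTEGER PRIMARY KEY AUTOINCREMENT,
    patient_id TEXT NOT NULL,
    encounter_id TEXT,
    concept_code TEXT NOT NULL,
    start_datetime TEXT NOT NULL,
    value_kind TEXT NOT NULL,
    numeric_value REAL,
    unit TEXT,
    text_value TEXT,
    provider_id TEXT,
    source_logic TEXT
);
CREATE INDEX IF NOT EXISTS idx_fact_concept ON observation_fact (concept_code);
CREATE INDEX IF NOT EXISTS idx_fact_patient ON observation_fact (patient_id);
CREATE TABLE IF NOT EXISTS logic_watermark (
    logic_name TEXT PRIMARY KEY,
    watermark TEXT
);
"""

_FACT_COLS = (
    "fact_id, patient_id, encounter_id, concept_code, start_datetime, "
    "value_kind, numeric_value, unit, text_value, provider_id, source_logic"
)


def normalize_operator(op: str) -> str:
    try:
        return OPERATORS[op]
    except KeyError:
        raise ConfigurationError(
            f"unsupported operator {op!r}; expected one of {sorted(set(OPERATORS))}"
        ) from None


class PatientStore:
    """Fact store with predicate-based retrieval.

    Parameters
    ----------
    path:
        SQLite file path, or ``":memory:"`` (default) for an ephemeral
        in-process store.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    # -- dimensions ---------------------------------------------------------

    def add_patients(self, patients: Iterable[PatientRecord]) -> int:
        rows = [
            (
                str(p.patient_id),
                p.birth_date.isoformat() if p.birth_date else None,
                p.sex,
            )
            for p in patients
        ]
        with self._conn:
            self._conn.executemany(
                "INSERT OR REPLACE INTO patient_dimension VALUES (?,?,?)", rows
            )
        return len(rows)

    def add_encounters(self, encounters: Iterable[EncounterRecord]) -> int:
        known = set(self.patient_ids())
        rows = []
        for e in encounters:
            if str(e.patient_id) not in known:
                raise NotFoundError(
                    f"encounter {e.encounter_id}: unknown patient {e.patient_id}"
                )
            rows.append(
                (
                    str(e.encounter_id),
                    str(e.patient_id),
                    format_datetime(parse_datetime(e.start_datetime))
                    if e.start_datetime
                    else None,
                    format_datetime(parse_datetime(e.end_datetime))
                    if e.end_datetime
                    else None,
                )
            )
        with self._conn:
            self._conn.executemany(
                "INSERT OR REPLACE INTO encounter_dimension VALUES (?,?,?,?)", rows
            )
        return len(rows)

    def patient_ids(self) -> list[str]:
        cur = self._conn.execute("SELECT patient_id FROM patient_dimension ORDER BY patient_id")
        return [r[0] for r in cur]

    def has_patient(self, patient_id: str) -> bool:
        cur = self._conn.execute(
            "SELECT 1 FROM patient_dimension WHERE patient_id = ?", (str(patient_id),)
        )
        return cur.fetchone() is not None

    # -- facts --------------------------------------------------------------

    def insert_facts(self, facts: Sequence[ObservationFact]) -> int:
        """Append a batch of facts atomically; returns the number inserted.

        Every fact is validated first; any invariant violation rejects the
        whole batch (all-or-nothing) with a row-level error naming the
        field. Unknown patients get stub dimension rows.
        """
        facts = list(facts)
        for i, fact in enumerate(facts):
            if not isinstance(fact, ObservationFact):
                raise FactValidationError("fact", f"not an ObservationFact: {fact!r}", i)
            fact.validate(row=i)
        rows = [
            (
                str(f.patient_id),
                None if f.encounter_id is None else str(f.encounter_id),
                f.concept_code,
                format_datetime(f.start_datetime),
                f.value_kind,
                f.numeric_value,
                f.unit,
                f.text_value,
                f.provider_id,
                f.source_logic,
            )
            for f in facts
        ]
        with self._conn:
            self._conn.executemany(
                "INSERT INTO patient_dimension (patient_id) VALUES (?) "
                "ON CONFLICT (patient_id) DO NOTHING",
                [(r[0],) for r in rows],
            )
            self._conn.executemany(
                "INSERT INTO observation_fact (patient_id, encounter_id, concept_code, "
                "start_datetime, value_kind, numeric_value, unit, text_value, "
                "provider_id, source_logic) VALUES (?,?,?,?,?,?,?,?,?,?)",
                rows,
            )
        return len(rows)

    def fact_count(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM observation_fact").fetchone()[0]

    def delete_facts(self, source_logic: str) -> int:
        """Remove all facts produced by a given Logic (recompute support)."""
        with self._conn:
            cur = self._conn.execute(
                "DELETE FROM observation_fact WHERE source_logic = ?", (source_logic,)
            )
        return cur.rowcount

    @staticmethod
    def _fact_from_row(row: tuple) -> ObservationFact:
        return ObservationFact(
            patient_id=row[1],
            encounter_id=row[2],
            concept_code=row[3],
            start_datetime=datetime.fromisoformat(row[4]),
            value_kind=row[5],
            numeric_value=row[6],
            unit=row[7],
            text_value=row[8],
            provider_id=row[9],
            source_logic=row[10] or "",
        )

    def all_facts(self) -> list[ObservationFact]:
        cur = self._conn.execute(
            f"SELECT {_FACT_COLS} FROM observation_fact ORDER BY fact_id"
        )
        return [self._fact_from_row(r) for r in cur]

    def distinct_codes(self, prefix: str | None = None) -> list[str]:
        if prefix is not None:
            cur = self._conn.execute(
                "SELECT DISTINCT concept_code FROM observation_fact "
                "WHERE concept_code LIKE ? ORDER BY concept_code",
                (prefix.replace("%", "") + "%",),
            )
        else:
            cur = self._conn.execute(
                "SELECT DISTINCT concept_code FROM observation_fact ORDER BY concept_code"
            )
        return [r[0] for r in cur]

    def query_facts(
        self,
        concept_codes: Iterable[str],
        value_predicate: tuple[str, float] | tuple[str] | str | None = None,
        window: tuple | None = None,
    ) -> list[ObservationFact]:
        """Pure filter over the fact table.

        Returns exactly the facts whose concept_code is in ``concept_codes``,
        whose start_datetime falls in the closed ``window`` (both ends
        inclusive), and whose numeric value satisfies ``value_predicate``
        (an ``(operator, threshold)`` pair). The ``exists`` operator ignores
        values; every other operator matches only numeric facts. Results
        come back in insertion order.
        """
        codes = sorted({str(c) for c in concept_codes})
        if not codes:
            return []
        clauses = [f"concept_code IN ({','.join('?' * len(codes))})"]
        params: list = list(codes)

        if window is not None:
            lo, hi = window
            lo, hi = parse_datetime(lo), parse_datetime(hi)
            if lo > hi:
                raise ConfigurationError(f"window endpoints out of order: {lo} > {hi}")
            clauses.append("start_datetime >= ? AND start_datetime <= ?")
            params += [format_datetime(lo), format_datetime(hi)]

        if value_predicate is not None:
            if isinstance(value_predicate, str):
                value_predicate = (value_predicate,)
            op = normalize_operator(value_predicate[0])
            if op != "exists":
                if len(value_predicate) < 2:
                    raise ConfigurationError(f"operator {op!r} requires a threshold")
                threshold = value_predicate[1]
                try:
                    threshold = float(threshold)
                except (TypeError, ValueError):
                    raise ConfigurationError(
                        f"numeric predicate threshold is not numeric: {threshold!r}"
                    ) from None
                clauses.append(f"value_kind = 'numeric' AND numeric_value {op} ?")
                params.append(threshold)

        sql = (
            f"SELECT {_FACT_COLS} FROM observation_fact WHERE "
            + " AND ".join(clauses)
            + " ORDER BY fact_id"
        )
        return [self._fact_from_row(r) for r in self._conn.execute(sql, params)]

    def patient_chart(self, patient_id: str) -> list[ObservationFact]:
        """All facts for a patient, chronologically; ties keep insertion order."""
        if not self.has_patient(str(patient_id)):
            raise NotFoundError(f"unknown patient {patient_id!r}")
        cur = self._conn.execute(
            f"SELECT {_FACT_COLS} FROM observation_fact WHERE patient_id = ? "
            "ORDER BY start_datetime, fact_id",
            (str(patient_id),),
        )
        return [self._fact_from_row(r) for r in cur]

    # -- watermarks ---------------------------------------------------------

    def get_watermark(self, logic_name: str):
        row = self._conn.execute(
            "SELECT watermark FROM logic_watermark WHERE logic_name = ?", (logic_name,)
        ).fetchone()
        return None if row is None or row[0] is None else json.loads(row[0])

    def set_watermark(self, logic_name: str, value) -> None:
        with self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO logic_watermark VALUES (?, ?)",
                (logic_name, json.dumps(value)),
            )

    # -- CSV interchange ----------------------------------------------------

    def export_csv(self, path: str) -> int:
        """Write the fact table as CSV with ISO-8601 timestamps."""
        facts = self.all_facts()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for f in facts:
                writer.writerow(
                    [
                        f.patient_id,
                        f.encounter_id or "",
                        f.concept_code,
                        format_datetime(f.start_datetime),
                        f.value_kind,
                        "" if f.numeric_value is None else repr(f.numeric_value),
                        f.unit or "",
                        f.text_value or "",
                        f.provider_id or "",
                        f.source_logic or "",
                    ]
                )
        return len(facts)

    def import_csv(self, path: str) -> int:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header != CSV_HEADER:
                raise ConfigurationError(
                    f"unexpected CSV header {header!r}; expected {CSV_HEADER!r}"
                )
            facts = [
                ObservationFact(
                    patient_id=r[0],
                    encounter_id=r[1] or None,
                    concept_code=r[2],
                    start_datetime=r[3],
                    value_kind=r[4],
                    numeric_value=float(r[5]) if r[5] else None,
                    unit=r[6] or None,
                    text_value=r[7] or None,
                    provider_id=r[8] or None,
                    source_logic=r[9],
                )
                for r in reader
            ]
        return self.insert_facts(facts)

    def close(self) -> None:
        self._conn.close()
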