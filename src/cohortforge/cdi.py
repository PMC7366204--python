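"""Reader/writer for the tab-separated i2b2-cdi interchange dialect.

One file carries both the concept metadata and the facts that reference
it, so a single import both extends the ontology and loads data. Line
format (UTF-8, tab-separated, column 1 is the line-type tag):

``C <TAB> path <TAB> code <TAB> name``
    concept node (code may be empty for folders);
``M <TAB> local_code <TAB> standard_code``
    local-to-standard code mapping;
``F <TAB> patient_id <TAB> encounter_id <TAB> concept_code <TAB>
start_datetime <TAB> value_kind <TAB> value <TAB> unit``
    observation fact (encounter_id, value, unit may be empty; flag facts
    leave value empty).

Blank lines and ``#`` comments are ignored. The writer emits concepts,
then mappings, then facts, and round-trips bit-exactly with the reader.
"""

from __future__ import annotations

import dataclasses

from .errors import LoadError
from .facts import ObservationFact, format_datetime, parse_datetime


@dataclasses.dataclass
class CdiDocument:
    concepts: list[tuple[str, str, str]]  # (path, code, name)
    mappings: list[tuple[str, str]]  # (local_code, standard_code)
    facts: list[ObservationFact]


def read_cdi(source) -> CdiDocument:
    close = False
    if isinstance(source, (str, bytes)):
        fh = open(source, encoding="utf-8")
        close = True
    else:
        fh = source
    concepts: list[tuple[str, str, str]] = []
    mappings: list[tuple[str, str]] = []
    facts: list[ObservationFact] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            tag = cols[0]
            if tag == "C":
                if len(cols) != 4:
                    raise LoadError(f"C line needs 4 columns, got {len(cols)}", lineno)
                concepts.append((cols[1], cols[2], cols[3]))
            elif tag == "M":
                if len(cols) != 3:
                    raise LoadError(f"M line needs 3 columns, got {len(cols)}", lineno)
                mappings.append((cols[1], cols[2]))
            elif tag == "F":
                if len(cols) != 8:
                    raise LoadError(f"F line needs 8 columns, got {len(cols)}", lineno)
                _, pid, enc, code, dt, kind, value, unit = cols
                numeric = None
                text = None
                if kind == "numeric":
                    try:
                        numeric = float(value)
                    except ValueError:
                        raise LoadError(f"non-numeric value {value!r}", lineno) from None
                elif kind == "text":
                    text = value
                elif kind == "flag":
                    if value:
                        raise LoadError("flag facts carry no value", lineno)
                else:
                    raise LoadError(f"unknown value_kind {kind!r}", lineno)
                facts.append(
                    ObservationFact(
                        patient_id=pid,
                        encounter_id=enc or None,
                        concept_code=code,
                        start_datetime=parse_datetime(dt),
                        value_kind=kind,
                        numeric_value=numeric,
                        unit=unit or None,
                        text_value=text,
                    )
                )
            else:
                raise LoadError(f"unknown line tag {tag!r}", lineno)
    finally:
        if close:
            fh.close()
    return CdiDocument(concepts=concepts, mappings=mappings, facts=facts)


def write_cdi(doc: CdiDocument, target) -> None:
    close = False
    if isinstance(target, (str, bytes)):
        fh = open(target, "w", encoding="utf-8")
        close = True
    else:
        fh = target
    try:
        for path, code, name in doc.concepts:
            fh.write(f"C\t{path}\t{code}\t{name}\n")
        for local, standard in doc.mappings:
            fh.write(f"M\t{local}\t{standard}\n")
        for f in doc.facts:
            value = ""
            if f.value_kind == "numeric":
                value = repr(float(f.numeric_value))
            elif f.value_kind == "text":
                value = f.text_value or ""
            dt = f.start_datetime
            dt_s = format_datetime(dt) if not isinstance(dt, str) else dt
            fh.write(
                "F\t{pid}\t{enc}\t{code}\t{dt}\t{kind}\t{value}\t{unit}\n".format(
                    pid=f.patient_id,
                    enc=f.encounter_id or "",
                    code=f.concept_code,
                    dt=dt_s,
                    kind=f.value_kind,
                    value=value,
                    unit=f.unit or "",
                )
            )
    finally:
        if close:
            fh.close()
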