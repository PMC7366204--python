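"""Logic catalogue and local pipeline orchestrator.

Executes registered Logics synchronously and records every run: which
Logic, what triggered it, row counts, the watermark after an incremental
import, and an ordered log. This replaces a managed cloud pipeline
service with the same run/trigger/log contract — registering a Logic is
cheap, running it reads from its source, transforms rows into
observation facts, writes them to the star schema, and leaves an
auditable PipelineRun behind.

Imports are batched (``batch_count`` rows per batch) and atomic per
batch: a malformed row fails its batch and the run, but batches already
written stay, matching restart practice for long loads. Watermarked
imports are idempotent — only source rows whose watermark value is
strictly greater than the stored mark are imported.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import sqlite3
from datetime import datetime
from typing import Any, Callable, Iterable, Optional

from . import cdi, derived
from .errors import (
    CohortForgeError,
    ConfigurationError,
    FactValidationError,
    LoadError,
    NotFoundError,
)
from .facts import ObservationFact
from .logics import (
    CdiFileSpec,
    DerivedConceptDef,
    Logic,
    ScriptSpec,
    SqlImportSpec,
    TsvFileSpec,
)
from .ontology import ConceptHierarchy
from .plugins import PluginRegistry
from .store import PatientStore


@dataclasses.dataclass
class PipelineRun:
    run_id: int
    logic_name: str
    trigger: str
    status: str = "running"  # running | succeeded | failed
    started: datetime = dataclasses.field(default_factory=datetime.now)
    finished: Optional[datetime] = None
    rows_read: int = 0
    rows_written: int = 0
    watermark_after: Any = None
    log: list[str] = dataclasses.field(default_factory=list)

    def log_msg(self, message: str) -> None:
        self.log.append(message)

    def finish(self, status: str) -> "PipelineRun":
        self.status = status
        self.finished = datetime.now()
        if status == "failed" and not self.log:
            self.log.append("run failed")
        return self


class LogicEngine:
    """Catalogue of Logics plus their executors.

    Parameters
    ----------
    store:
        target :class:`PatientStore`.
    hierarchy:
        concept catalogue shared by all Logics (created empty if omitted).
    plugins:
        registry for script-modality Logics and per-row transforms.
    """

    def __init__(
        self,
        store: PatientStore,
        hierarchy: ConceptHierarchy | None = None,
        plugins: PluginRegistry | None = None,
    ):
        self.store = store
        self.hierarchy = hierarchy if hierarchy is not None else ConceptHierarchy()
        self.plugins = plugins if plugins is not None else PluginRegistry()
        self._catalogue: dict[str, Logic] = {}
        self.catalogue_log: list[str] = []
        self.runs: list[PipelineRun] = []

    # -- catalogue ----------------------------------------------------------

    def register_logic(self, logic: Logic | dict) -> Logic:
        """Validate and catalogue a Logic; re-registering replaces (logged)."""
        if isinstance(logic, dict):
            logic = Logic.model_validate(logic)
        logic.typed_spec()  # validates the type/modality spec combination
        action = "replaced" if logic.name in self._catalogue else "registered"
        self._catalogue[logic.name] = logic
        self.catalogue_log.append(f"{action} {logic.logic_type} logic {logic.name!r}")
        return logic

    def get_logic(self, name: str) -> Logic:
        try:
            return self._catalogue[name]
        except KeyError:
            raise NotFoundError(f"no logic registered under {name!r}") from None

    def list_logics(self, prefix: str | None = None) -> list[Logic]:
        logics = sorted(self._catalogue.values(), key=lambda l: (l.logic_path, l.name))
        if prefix is None:
            return logics
        p = prefix.strip().strip("/")
        return [
            l for l in logics if l.logic_path == p or l.logic_path.startswith(p + "/")
        ]

    def get_run(self, run_id: int) -> PipelineRun:
        for run in self.runs:
            if run.run_id == run_id:
                return run
        raise NotFoundError(f"no run {run_id}")

    # -- execution ----------------------------------------------------------

    def run_logic(self, name: str, trigger: str = "manual") -> PipelineRun:
        """Execute one Logic by name and record the run."""
        logic = self.get_logic(name)
        run = PipelineRun(run_id=len(self.runs) + 1, logic_name=name, trigger=trigger)
        self.runs.append(run)
        executor = self._executor_for(logic)
        try:
            executor(logic, run)
        except CohortForgeError as exc:
            run.log_msg(f"error: {exc}")
            return run.finish("failed")
        return run.finish("succeeded")

    def run_due(self) -> list[PipelineRun]:
        """Run every Logic carrying a schedule tag (explicit poll, no daemon)."""
        return [
            self.run_logic(logic.name, trigger="scheduled")
            for logic in self.list_logics()
            if logic.schedule
        ]

    def run_all_derived(self, trigger: str = "manual") -> list[PipelineRun]:
        """Run every derived-concept Logic in dependency order.

        Any circular dependency is detected before anything executes.
        """
        derived_logics = [
            l for l in self.list_logics() if l.logic_type == "derived_concept"
        ]
        defs = {l.name: l.typed_spec() for l in derived_logics}
        order = derived.plan_execution(list(defs.values()))
        name_for_def = {id(d): n for n, d in defs.items()}
        return [
            self.run_logic(name_for_def[id(d)], trigger=trigger) for d in order
        ]

    def _executor_for(self, logic: Logic) -> Callable[[Logic, PipelineRun], None]:
        if logic.logic_type == "import":
            return {
                "sql": self._run_import_sql,
                "cdi_file": self._run_import_cdi,
                "script": self._run_import_script,
            }[logic.modality]
        if logic.logic_type == "concept_hierarchy":
            return self._run_concept_hierarchy
        if logic.logic_type == "code_map":
            return self._run_code_map
        return self._run_derived_concept

    # -- executors ----------------------------------------------------------

    @staticmethod
    def _mapped_value(mapping_entry, row: dict):
        if isinstance(mapping_entry, str):
            return row[mapping_entry]
        if isinstance(mapping_entry, dict):
            if "const" in mapping_entry:
                return mapping_entry["const"]
            value = row[mapping_entry["column"]]
            if value is not None and mapping_entry.get("prefix"):
                value = f"{mapping_entry['prefix']}{value}"
            return value
        raise ConfigurationError(f"bad mapping entry {mapping_entry!r}")

    def _row_to_facts(
        self,
        spec: SqlImportSpec,
        row: dict,
        logic_name: str,
        algorithm: Callable | None,
        rewrite: dict[str, str],
    ) -> list[ObservationFact]:
        if algorithm is not None:
            facts = list(algorithm(row) or [])
        else:
            fields: dict[str, Any] = {}
            for field, entry in spec.mapping.items():
                fields[field] = self._mapped_value(entry, row)
            if "value_kind" not in fields:
                fields["value_kind"] = (
                    "numeric" if fields.get("numeric_value") is not None else "flag"
                )
            facts = [ObservationFact(**fields)]
        for fact in facts:
            fact.source_logic = logic_name
            if rewrite:
                fact.concept_code = rewrite.get(fact.concept_code, fact.concept_code)
        return facts

    def _run_import_sql(self, logic: Logic, run: PipelineRun) -> None:
        spec: SqlImportSpec = logic.typed_spec()
        conn = sqlite3.connect(spec.source)
        try:
            cursor = conn.execute(spec.extract_query)
            columns = [d[0] for d in cursor.description]
            for field, entry in spec.mapping.items():
                col = entry if isinstance(entry, str) else (
                    entry.get("column") if isinstance(entry, dict) else None
                )
                if col is not None and col not in columns:
                    raise ConfigurationError(
                        f"mapped column {col!r} (field {field!r}) not in extract "
                        f"result columns {columns}"
                    )
            if spec.watermark_field and spec.watermark_field not in columns:
                raise ConfigurationError(
                    f"watermark_field {spec.watermark_field!r} not in extract columns"
                )

            rewrite: dict[str, str] = {}
            if spec.concept_mapping:
                rewrite = _load_flat_mapping(
                    spec.concept_mapping, spec.concept_mapping_direction
                )
                run.log_msg(
                    f"loaded {len(rewrite)} concept mapping entries "
                    f"({spec.concept_mapping_direction})"
                )
            algorithm = self.plugins.get(spec.algorithm) if spec.algorithm else None

            stored_wm = self.store.get_watermark(logic.name)
            rows = []
            for raw in cursor:
                run.rows_read += 1
                row = dict(zip(columns, raw))
                if spec.watermark_field is not None:
                    wm_value = row[spec.watermark_field]
                    if stored_wm is not None and not (wm_value > stored_wm):
                        continue
                rows.append((run.rows_read, row))

            new_wm = stored_wm
            batches = [
                rows[i : i + spec.batch_count]
                for i in range(0, len(rows), spec.batch_count)
            ]
            for batch_no, batch in enumerate(batches, start=1):
                facts: list[ObservationFact] = []
                try:
                    for rowno, row in batch:
                        try:
                            for fact in self._row_to_facts(
                                spec, row, logic.name, algorithm, rewrite
                            ):
                                fact.validate()
                                facts.append(fact)
                        except (FactValidationError, KeyError, TypeError) as exc:
                            raise ConfigurationError(
                                f"row {rowno}: {exc}"
                            ) from exc
                    written = self.store.insert_facts(facts)
                except CohortForgeError as exc:
                    run.log_msg(f"batch {batch_no} failed: {exc}")
                    if new_wm is not None:
                        self.store.set_watermark(logic.name, new_wm)
                        run.watermark_after = new_wm
                    raise
                run.rows_written += written
                run.log_msg(f"batch {batch_no}: wrote {written} facts")
                if spec.watermark_field is not None:
                    batch_max = max(row[spec.watermark_field] for _, row in batch)
                    new_wm = batch_max if new_wm is None else max(new_wm, batch_max)
            if spec.watermark_field is not None and new_wm is not None:
                self.store.set_watermark(logic.name, new_wm)
                run.watermark_after = new_wm
            run.log_msg(
                f"import complete: read {run.rows_read}, wrote {run.rows_written}"
            )
        finally:
            conn.close()

    def _run_import_cdi(self, logic: Logic, run: PipelineRun) -> None:
        spec: CdiFileSpec = logic.typed_spec()
        doc = cdi.read_cdi(spec.file)
        run.rows_read = len(doc.concepts) + len(doc.mappings) + len(doc.facts)

        # Validate everything against (existing hierarchy + file metadata)
        # BEFORE mutating anything, so a single file import is atomic.
        declared = {code for _, code, _ in doc.concepts if code}
        declared |= {local for local, _ in doc.mappings}
        for i, fact in enumerate(doc.facts):
            fact.validate(row=i)
            code = fact.concept_code
            if code in declared or self.hierarchy.paths_for_code(code):
                continue
            raise LoadError(
                f"fact references undeclared concept code {code!r} "
                "(not in file metadata or existing hierarchy)"
            )

        for path, code, name in doc.concepts:
            self.hierarchy.add_node(path, code=code, name=name)
        for local, standard in doc.mappings:
            self.hierarchy.add_local_mapping(local, standard)
        for fact in doc.facts:
            fact.source_logic = logic.name
        run.rows_written = self.store.insert_facts(doc.facts)
        run.log_msg(
            f"cdi import: {len(doc.concepts)} concepts, {len(doc.mappings)} "
            f"mappings, {run.rows_written} facts"
        )

    def _run_import_script(self, logic: Logic, run: PipelineRun) -> None:
        spec: ScriptSpec = logic.typed_spec()
        plugin = self.plugins.get(spec.plugin)
        facts = list(plugin() or [])
        run.rows_read = len(facts)
        for fact in facts:
            fact.source_logic = logic.name
        run.rows_written = self.store.insert_facts(facts)
        run.log_msg(f"script import wrote {run.rows_written} facts")

    def _run_concept_hierarchy(self, logic: Logic, run: PipelineRun) -> None:
        spec: TsvFileSpec = logic.typed_spec()
        before = len(self.hierarchy)
        if spec.separator == "\\":
            with open(spec.file, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
            translated = [lines[0]] + [
                line.replace("\\", "/") for line in lines[1:]
            ]
            run.rows_read = self.hierarchy.merge_tsv(io.StringIO("\n".join(translated) + "\n"))
        else:
            run.rows_read = self.hierarchy.merge_tsv(spec.file)
        run.log_msg(
            f"hierarchy now {len(self.hierarchy)} nodes (+{len(self.hierarchy) - before})"
        )

    def _run_code_map(self, logic: Logic, run: PipelineRun) -> None:
        spec: TsvFileSpec = logic.typed_spec()
        run.rows_read = self.hierarchy.merge_mapping_tsv(spec.file)
        run.log_msg(f"applied {run.rows_read} local-code mappings")

    def _run_derived_concept(self, logic: Logic, run: PipelineRun) -> None:
        defn: DerivedConceptDef = logic.typed_spec()
        written = derived.materialize(
            defn, self.store, self.hierarchy, self.plugins, log=run.log
        )
        run.rows_written = written
        run.rows_read = max(written, run.rows_read)
        run.log_msg(f"derived concept {defn.output_code}: {written} facts")


def _load_flat_mapping(path: str, direction: str) -> dict[str, str]:
    """Read a ``local_code<TAB>standard_code`` TSV into a rewrite table."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != ["local_code", "standard_code"]:
            raise LoadError(f"bad mapping header {header!r}", 1)
        for local, standard in reader:
            if direction == "local_to_standard":
                table[local] = standard
            else:
                table.setdefault(standard, local)
    return table
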