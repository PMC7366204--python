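"""Logic catalogue and pipeline orchestration: imports, watermarks, cdi."""

import sqlite3

import pytest

from cohortforge import diabetes, synth
from cohortforge.engine import LogicEngine
from cohortforge.errors import NotFoundError
from cohortforge.facts import ObservationFact
from cohortforge.logics import Logic
from cohortforge.store import PatientStore

LAB_ROWS = [
    # (subject_id, hadm_id, loinc_code, charttime, valuenum, valueuom)
    ("p1", "e1", "2345-7", "2020-01-01T08:00:00", 100.0, "mg/dL"),
    ("p1", "e1", "2345-7", "2020-02-01T08:00:00", 180.0, "mg/dL"),
    ("p2", "e2", "2345-7", "2020-01-15T09:00:00", 95.0, "mg/dL"),
    ("p2", "e2", "4548-4", "2020-03-01T09:00:00", 5.5, "%"),
    ("p3", "e3", "2345-7", "2020-04-01T10:00:00", 130.0, "mg/dL"),
]


def make_staging(path, rows=LAB_ROWS, table="labevents"):
    conn = sqlite3.connect(path)
    with conn:
        conn.execute(
            f"CREATE TABLE IF NOT EXISTS {table} ("
            "row_id INTEGER PRIMARY KEY AUTOINCREMENT, subject_id TEXT, hadm_id TEXT, "
            "loinc_code TEXT, charttime TEXT, valuenum REAL, valueuom TEXT)"
        )
        conn.executemany(
            f"INSERT INTO {table} (subject_id, hadm_id, loinc_code, charttime, "
            "valuenum, valueuom) VALUES (?,?,?,?,?,?)",
            rows,
        )
    conn.close()
    return path


def labs_logic(source, batch_count=1000, watermark="row_id", name="Labs-import"):
    return Logic(
        name=name,
        logic_type="import",
        logic_path=f"Import/{name}",
        modality="sql",
        spec={
            "source": str(source),
            "extract_query": (
                "SELECT row_id, subject_id, hadm_id, loinc_code, charttime, "
                "valuenum, valueuom FROM labevents ORDER BY row_id"
            ),
            "watermark_field": watermark,
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
    )


@pytest.fixture
def engine(store):
    return LogicEngine(store)


class TestCatalogue:
    def test_registered_logic_listed_under_prefix(self, engine, tmp_path):
        make_staging(tmp_path / "s.db")
        engine.register_logic(labs_logic(tmp_path / "s.db", name="Diagnosis-import"))
        assert [l.name for l in engine.list_logics(prefix="Import/")] == [
            "Diagnosis-import"
        ]

    def test_empty_catalogue_lists_empty(self, engine):
        assert engine.list_logics() == []

    def test_full_catalogue_partitions_by_path_prefix(self, engine, tmp_path):
        staging = make_staging(tmp_path / "s.db")
        labs_tsv = tmp_path / "labs.tsv"
        dx_tsv = tmp_path / "dx.tsv"
        synth.write_labs_hierarchy_tsv(str(labs_tsv))
        synth.write_diagnosis_hierarchy_tsv(str(dx_tsv))
        logics = diabetes.all_logics(str(staging), str(dx_tsv), str(labs_tsv))
        for logic in logics:
            engine.register_logic(logic)
        by_prefix = {
            prefix: {l.name for l in engine.list_logics(prefix=prefix)}
            for prefix in ("Import", "Concept_Hierarchy", "Derived_Concept", "Labs")
        }
        assert by_prefix["Import"] == {"Diagnosis-import", "Labs-import"}
        assert by_prefix["Concept_Hierarchy"] == {
            "Diagnosis-hierarchy",
            "Labs-hierarchy",
        }
        assert by_prefix["Derived_Concept"] == {"Diagnosis-Diabetes"}
        assert by_prefix["Labs"] == {
            "Last-HbA1c",
            "Last-Glucose",
            "Last-Two-Glucose-High",
        }
        # partition: every logic appears under exactly its own prefix chain
        assert sum(len(v) for v in by_prefix.values()) == len(logics)

    def test_invalid_type_modality_combination_rejected(self):
        with pytest.raises(Exception, match="combination"):
            Logic(
                name="bad",
                logic_type="concept_hierarchy",
                logic_path="X/bad",
                modality="sql",
                spec={},
            )

    def test_reregistering_replaces_and_logs(self, engine, tmp_path):
        make_staging(tmp_path / "s.db")
        engine.register_logic(labs_logic(tmp_path / "s.db"))
        engine.register_logic(labs_logic(tmp_path / "s.db", batch_count=7))
        assert engine.get_logic("Labs-import").typed_spec().batch_count == 7
        assert any("replaced" in msg for msg in engine.catalogue_log)

    def test_run_unknown_logic_not_found(self, engine):
        with pytest.raises(NotFoundError):
            engine.run_logic("ghost")


class TestSqlImport:
    def test_lossless_import_of_five_rows(self, engine, tmp_path):
        engine.register_logic(labs_logic(make_staging(tmp_path / "s.db")))
        run = engine.run_logic("Labs-import")
        assert (run.status, run.rows_read, run.rows_written) == ("succeeded", 5, 5)
        assert engine.store.fact_count() == 5
        codes = {f.concept_code for f in engine.store.all_facts()}
        assert codes == {"LOINC:2345-7", "LOINC:4548-4"}

    def test_malformed_third_row_fails_run_keeping_prior_batches(self, engine, tmp_path):
        rows = list(LAB_ROWS)
        rows[2] = ("p2", "e2", "2345-7", "not-a-date", 95.0, "mg/dL")
        engine.register_logic(labs_logic(make_staging(tmp_path / "s.db", rows), batch_count=1))
        run = engine.run_logic("Labs-import")
        assert run.status == "failed"
        assert run.rows_written == 2  # per-batch atomicity keeps batches 1-2
        assert any("row 3" in msg for msg in run.log)
        assert engine.store.fact_count() == 2

    def test_ten_rows_batch_three_gives_four_batches(self, engine, tmp_path):
        rows = [(f"p{i}", f"e{i}", "2345-7", f"2020-01-{i + 1:02d}T00:00:00", 100.0 + i, "mg/dL")
                for i in range(10)]
        engine.register_logic(labs_logic(make_staging(tmp_path / "s.db", rows), batch_count=3))
        run = engine.run_logic("Labs-import")
        batch_msgs = [m for m in run.log if m.startswith("batch")]
        assert len(batch_msgs) == 4  # ceil(10 / 3)
        assert run.rows_written == 10

    def test_watermarked_rerun_on_unchanged_source_writes_nothing(self, engine, tmp_path):
        staging = make_staging(tmp_path / "s.db")
        engine.register_logic(labs_logic(staging))
        first = engine.run_logic("Labs-import")
        second = engine.run_logic("Labs-import")
        assert first.rows_written == 5
        assert second.rows_written == 0
        assert engine.store.fact_count() == 5
        assert second.watermark_after == first.watermark_after

    def test_appended_rows_imported_incrementally_without_duplicates(self, engine, tmp_path):
        staging = make_staging(tmp_path / "s.db")
        engine.register_logic(labs_logic(staging))
        engine.run_logic("Labs-import")
        new_rows = [
            (f"p{i}", f"e{i}", "2345-7", f"2020-06-0{i}T00:00:00", 110.0 + i, "mg/dL")
            for i in range(1, 5)
        ]
        make_staging(staging, new_rows)  # append 4 more
        run = engine.run_logic("Labs-import")
        assert run.rows_written == 4
        assert engine.store.fact_count() == 14 - 5  # 9 total facts
        keys = [f.key() for f in engine.store.all_facts()]
        assert len(keys) == len(set(keys))  # no duplicates

    def test_missing_mapped_column_fails_before_any_write(self, engine, tmp_path):
        logic = labs_logic(make_staging(tmp_path / "s.db"))
        logic.spec["mapping"]["numeric_value"] = "no_such_column"
        engine.register_logic(logic)
        run = engine.run_logic("Labs-import")
        assert run.status == "failed"
        assert run.rows_written == 0
        assert engine.store.fact_count() == 0

    def test_ingest_time_concept_mapping_rewrites_codes(self, engine, tmp_path):
        rows = [("p1", "e1", "glu-local", "2020-01-01T00:00:00", 99.0, "mg/dL")]
        logic = labs_logic(make_staging(tmp_path / "s.db", rows))
        mapping = tmp_path / "map.tsv"
        mapping.write_text("local_code\tstandard_code\nLOINC:glu-local\tLOINC:2345-7\n")
        logic.spec["concept_mapping"] = str(mapping)
        engine.register_logic(logic)
        run = engine.run_logic("Labs-import")
        assert run.status == "succeeded"
        assert engine.store.all_facts()[0].concept_code == "LOINC:2345-7"

    def test_per_row_algorithm_plugin(self, engine, tmp_path):
        engine.register_logic(labs_logic(make_staging(tmp_path / "s.db")))
        logic = engine.get_logic("Labs-import")
        logic.spec["algorithm"] = "double"

        @engine.plugins.register("double")
        def double(row):
            # emit two facts per source row
            base = dict(
                patient_id=row["subject_id"],
                concept_code=f"LOINC:{row['loinc_code']}",
                start_datetime=row["charttime"],
                value_kind="numeric",
                numeric_value=row["valuenum"],
            )
            return [ObservationFact(**base), ObservationFact(**base)]

        run = engine.run_logic("Labs-import")
        assert run.status == "succeeded"
        assert run.rows_written == 10  # 2 per source row


class TestCdiImport:
    CDI = (
        "C\tLabs\t\tLabs\n"
        "C\tLabs/Glucose\tLOINC:2345-7\tGlucose\n"
        "F\tp1\te1\tLOINC:2345-7\t2020-01-01T08:00:00\tnumeric\t100.0\tmg/dL\n"
        "F\tp1\te1\tLOINC:2345-7\t2020-02-01T08:00:00\tnumeric\t180.0\tmg/dL\n"
    )

    def cdi_logic(self, path):
        return Logic(
            name="cdi-import",
            logic_type="import",
            logic_path="Import/cdi-import",
            modality="cdi_file",
            spec={"file": str(path)},
        )

    def test_concepts_then_facts(self, engine, tmp_path):
        f = tmp_path / "d.cdi"
        f.write_text(self.CDI)
        engine.register_logic(self.cdi_logic(f))
        run = engine.run_logic("cdi-import")
        assert run.status == "succeeded"
        assert run.rows_written == 2
        assert "Labs/Glucose" in engine.hierarchy
        assert engine.store.fact_count() == 2

    def test_concept_only_file_grows_hierarchy_writes_nothing(self, engine, tmp_path):
        f = tmp_path / "d.cdi"
        f.write_text("C\tLabs\t\tLabs\nC\tLabs/Glucose\tLOINC:2345-7\tGlucose\n")
        engine.register_logic(self.cdi_logic(f))
        run = engine.run_logic("cdi-import")
        assert run.rows_written == 0
        assert len(engine.hierarchy) == 2

    def test_mapping_lines_extend_hierarchy_before_facts(self, engine, tmp_path):
        f = tmp_path / "d.cdi"
        f.write_text(
            "C\tLabs/Glucose\tLOINC:2345-7\tGlucose\n"
            "M\tLOCAL:g1\tLOINC:2345-7\n"
            "F\tp1\t\tLOCAL:g1\t2020-01-01T00:00:00\tnumeric\t88.0\tmg/dL\n"
        )
        engine.register_logic(self.cdi_logic(f))
        run = engine.run_logic("cdi-import")
        assert run.status == "succeeded"
        assert "LOCAL:g1" in engine.hierarchy.expand("LOINC:2345-7")

    def test_undeclared_concept_fails_atomically(self, engine, tmp_path):
        f = tmp_path / "d.cdi"
        f.write_text(
            "C\tLabs/Glucose\tLOINC:2345-7\tGlucose\n"
            "F\tp1\t\tLOINC:9999-9\t2020-01-01T00:00:00\tnumeric\t88.0\t\n"
        )
        engine.register_logic(self.cdi_logic(f))
        run = engine.run_logic("cdi-import")
        assert run.status == "failed"
        assert any("LOINC:9999-9" in msg for msg in run.log)
        assert engine.store.fact_count() == 0
        assert len(engine.hierarchy) == 0  # atomic: hierarchy untouched too

    def test_generator_cdi_matches_direct_insert_path(self, tmp_path):
        dataset = synth.generate(synth.SynthConfig(n_patients=20, seed=5))
        direct = PatientStore()
        synth.load_direct(dataset, direct)

        f = tmp_path / "d.cdi"
        synth.write_cdi(dataset, str(f))
        via_cdi = LogicEngine(PatientStore())
        via_cdi.register_logic(self.cdi_logic(f))
        run = via_cdi.run_logic("cdi-import")
        assert run.status == "succeeded"
        assert sorted(f.key() for f in via_cdi.store.all_facts()) == sorted(
            f.key() for f in direct.all_facts()
        )


class TestScriptImportAndScheduling:
    def test_script_import_plugin(self, engine):
        @engine.plugins.register("feed")
        def feed():
            return [
                ObservationFact("p1", "LOINC:2345-7", "2020-01-01", "numeric",
                                numeric_value=100.0)
            ]

        engine.register_logic(
            Logic(
                name="scripted",
                logic_type="import",
                logic_path="Import/scripted",
                modality="script",
                spec={"plugin": "feed"},
            )
        )
        run = engine.run_logic("scripted")
        assert (run.status, run.rows_written) == ("succeeded", 1)

    def test_run_due_runs_only_scheduled_logics(self, engine, tmp_path):
        staging = make_staging(tmp_path / "s.db")
        scheduled = labs_logic(staging, name="nightly")
        scheduled.schedule = "daily"
        engine.register_logic(scheduled)
        engine.register_logic(labs_logic(staging, name="manual-only"))
        runs = engine.run_due()
        assert [r.logic_name for r in runs] == ["nightly"]
        assert runs[0].trigger == "scheduled"
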