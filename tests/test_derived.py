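"""Derived concepts: dependency planning, operators, recompute semantics."""

import random
from datetime import datetime, timedelta

import pytest

from cohortforge import derived, synth
from cohortforge.engine import LogicEngine
from cohortforge.errors import CycleError
from cohortforge.facts import ObservationFact
from cohortforge.logics import DerivedConceptDef, Logic
from cohortforge.ontology import ConceptHierarchy

from conftest import dx, lab


def last_value_def(name="Last-Glucose", source="LOINC:2345-7"):
    return DerivedConceptDef(
        name=name,
        concept_path=f"Derived/Labs/{name}",
        result_kind="numeric",
        operator="last_value",
        source=source,
    )


def last_n_def(n=2, comparator=">", threshold=126.0, source="LOINC:2345-7"):
    return DerivedConceptDef(
        name="Last-Two-High",
        concept_path="Derived/Labs/LastTwoHigh",
        result_kind="boolean",
        operator="last_n_consecutive_compare",
        source=source,
        n=n,
        comparator=comparator,
        threshold=threshold,
    )


class TestPlanExecution:
    def test_dependent_def_follows_its_source(self):
        last = last_value_def(name="LastHbA1c", source="LOINC:4548-4")
        flag = DerivedConceptDef(
            name="DiabetesByHbA1c",
            concept_path="Derived/Diagnosis/DiabetesByHbA1c",
            result_kind="boolean",
            operator="compare_derived",
            source="DERIVED:LastHbA1c",
            comparator=">",
            threshold=6.4,
        )
        order = derived.plan_execution([flag, last])
        assert [d.name for d in order] == ["LastHbA1c", "DiabetesByHbA1c"]

    def test_independent_defs_ordered_by_name(self):
        a = last_value_def(name="B-second")
        b = last_value_def(name="A-first")
        assert [d.name for d in derived.plan_execution([a, b])] == [
            "A-first",
            "B-second",
        ]

    def test_cycle_detected_and_named_nothing_executes(self):
        a = DerivedConceptDef(
            name="A", concept_path="D/A", result_kind="boolean",
            operator="compare_derived", source="DERIVED:B", comparator=">", threshold=0,
        )
        b = DerivedConceptDef(
            name="B", concept_path="D/B", result_kind="boolean",
            operator="compare_derived", source="DERIVED:A", comparator=">", threshold=0,
        )
        with pytest.raises(CycleError) as exc:
            derived.plan_execution([a, b])
        assert set(exc.value.cycle) == {"A", "B"}


class TestLastValue:
    def test_last_by_date_is_copied(self, store):
        store.insert_facts([lab("p1", 100, "2020-01-01"), lab("p1", 180, "2020-02-01")])
        out = derived.compute_last_value(last_value_def(), store)
        assert len(out) == 1
        assert out[0].numeric_value == 180.0
        assert out[0].start_datetime == datetime(2020, 2, 1)

    def test_single_fact_is_its_own_last(self, store):
        store.insert_facts([lab("p1", 95, "2020-01-01")])
        out = derived.compute_last_value(last_value_def(), store)
        assert out[0].numeric_value == 95.0

    def test_patient_without_source_facts_gets_no_fact(self, store):
        store.insert_facts([lab("p1", 95, "2020-01-01", code="LOINC:other")])
        assert derived.compute_last_value(last_value_def(), store) == []

    def test_non_numeric_only_patients_skipped_with_warning(self, store):
        store.insert_facts(
            [ObservationFact("p1", "LOINC:2345-7", "2020-01-01", "text", text_value="high")]
        )
        log = []
        assert derived.compute_last_value(last_value_def(), store, log=log) == []
        assert any("p1" in msg for msg in log)

    def test_shuffled_insertion_matches_max_by_date_brute_force(self, store):
        rng = random.Random(42)
        t0 = datetime(2020, 1, 1)
        expected = {}
        facts = []
        for i in range(100):
            pid = f"p{i:03d}"
            times = rng.sample(range(5000), rng.randint(1, 8))
            series = [(t0 + timedelta(hours=h), round(rng.uniform(50, 250), 1)) for h in times]
            expected[pid] = max(series, key=lambda p: p[0])[1]
            facts += [lab(pid, v, when) for when, v in series]
        rng.shuffle(facts)
        store.insert_facts(facts)
        out = derived.compute_last_value(last_value_def(), store)
        assert {f.patient_id: f.numeric_value for f in out} == expected

    def test_date_tie_resolved_by_insertion_order(self, store):
        store.insert_facts(
            [lab("p1", 111, "2020-01-01T08:00:00"), lab("p1", 222, "2020-01-01T08:00:00")]
        )
        out = derived.compute_last_value(last_value_def(), store)
        assert out[0].numeric_value == 222.0  # later-inserted wins the tie


class TestLastNConsecutiveCompare:
    def test_last_two_high_emits_flag(self, store):
        store.insert_facts([lab("p1", 130, "2020-01-01"), lab("p1", 140, "2020-02-01")])
        out = derived.compute_last_n_consecutive_compare(last_n_def(), store)
        assert [f.patient_id for f in out] == ["p1"]
        assert out[0].value_kind == "flag"
        assert out[0].start_datetime == datetime(2020, 2, 1)

    def test_fewer_than_n_facts_never_flags(self, store):
        store.insert_facts([lab("p1", 130, "2020-01-01")])
        assert derived.compute_last_n_consecutive_compare(last_n_def(), store) == []

    def test_dip_in_final_pair_prevents_flag(self, store):
        store.insert_facts(
            [lab("p1", 200, "2020-01-01"), lab("p1", 100, "2020-02-01"),
             lab("p1", 150, "2020-03-01")]
        )
        assert derived.compute_last_n_consecutive_compare(last_n_def(), store) == []

    def test_only_the_final_n_are_tested_not_any_n(self, store):
        # the adjacent pair (200, 180) would pass; the LAST pair (180, 100)
        # must be the one tested, and 100 <= 126 fails it
        store.insert_facts(
            [lab("p1", 200, "2020-01-01"), lab("p1", 180, "2020-02-01"),
             lab("p1", 100, "2020-03-01")]
        )
        assert derived.compute_last_n_consecutive_compare(last_n_def(), store) == []
        # brute-force window enumeration confirms an earlier window passes
        values = [200, 180, 100]
        windows = [values[i : i + 2] for i in range(len(values) - 1)]
        assert any(all(v > 126 for v in w) for w in windows)

    def test_values_exactly_at_threshold_excluded_by_strict_greater(self, store):
        store.insert_facts([lab("p1", 126, "2020-01-01"), lab("p1", 126, "2020-02-01")])
        assert derived.compute_last_n_consecutive_compare(last_n_def(), store) == []


class TestAnyCodePresent:
    def any_dx_def(self, **kwargs):
        params = dict(code_prefix="ICD9:250")
        params.update(kwargs)
        return DerivedConceptDef(
            name="Dx-Diabetes",
            concept_path="Derived/Diagnosis/Diabetes",
            result_kind="boolean",
            operator="any_code_present",
            **params,
        )

    def test_prefix_match_flags_patient_at_earliest_fact(self, store):
        store.insert_facts(
            [dx("p1", "ICD9:250.00", "2020-05-01"), dx("p1", "ICD9:250.00", "2020-01-01")]
        )
        out = derived.compute_any_code_present(self.any_dx_def(), store)
        assert out[0].start_datetime == datetime(2020, 1, 1)

    def test_lab_only_patients_not_flagged(self, store):
        store.insert_facts([lab("p1", 100, "2020-01-01")])
        assert derived.compute_any_code_present(self.any_dx_def(), store) == []

    def test_hierarchy_path_expansion(self, store):
        h = ConceptHierarchy()
        h.add_node("Diagnoses/Diabetes/250.00", code="ICD9:250.00")
        store.insert_facts([dx("p1", "ICD9:250.00", "2020-01-01")])
        out = derived.compute_any_code_present(
            self.any_dx_def(code_prefix=None, path="Diagnoses/Diabetes"), store, h
        )
        assert [f.patient_id for f in out] == ["p1"]

    def test_planted_diagnoses_recovered_exactly(self, store):
        dataset = synth.generate(synth.SynthConfig(n_patients=500, seed=9))
        synth.load_direct(dataset, store)
        out = derived.compute_any_code_present(self.any_dx_def(), store)
        assert {f.patient_id for f in out} == dataset.ground_truth.diagnosis_criterion


class TestScriptOperator:
    def script_def(self, plugin="mylast"):
        return DerivedConceptDef(
            name="Scripted",
            concept_path="Derived/Scripted",
            result_kind="numeric",
            operator="script",
            plugin=plugin,
        )

    def test_constant_flag_plugin_emits_one_fact_per_patient(self, store):
        from cohortforge.plugins import PluginRegistry

        store.insert_facts([lab(f"p{i}", 100, "2020-01-01") for i in range(5)])
        plugins = PluginRegistry()

        @plugins.register("mylast")
        def constant(pid, chart):
            return [
                ObservationFact(pid, "DERIVED:Scripted", "2020-01-01", "numeric",
                                numeric_value=1.0)
            ]

        out = derived.compute_script(self.script_def(), store, plugins=plugins)
        assert len(out) == 5

    def test_plugin_reimplementing_last_value_matches_builtin(self, store, rng):
        from cohortforge.plugins import PluginRegistry

        t0 = datetime(2020, 1, 1)
        facts = []
        for i in range(50):
            for h in rng.sample(range(2000), rng.randint(1, 6)):
                facts.append(lab(f"p{i}", round(rng.uniform(60, 250), 1), t0 + timedelta(hours=h)))
        store.insert_facts(facts)
        plugins = PluginRegistry()

        @plugins.register("mylast")
        def my_last(pid, chart):
            glu = [f for f in chart if f.concept_code == "LOINC:2345-7"]
            if not glu:
                return []
            return [
                ObservationFact(pid, "DERIVED:Scripted", glu[-1].start_datetime,
                                "numeric", numeric_value=glu[-1].numeric_value)
            ]

        scripted = derived.compute_script(self.script_def(), store, plugins=plugins)
        builtin = derived.compute_last_value(last_value_def(name="Scripted"), store)
        assert {(f.patient_id, f.numeric_value, f.start_datetime) for f in scripted} == {
            (f.patient_id, f.numeric_value, f.start_datetime) for f in builtin
        }

    def test_plugin_exception_fails_run_naming_patient(self, store):
        store.insert_facts([lab("p1", 100, "2020-01-01"), lab("p2", 100, "2020-01-01")])
        engine = LogicEngine(store)

        @engine.plugins.register("boom")
        def boom(pid, chart):
            if pid == "p2":
                raise ValueError("bad chart")
            return []

        engine.register_logic(
            Logic(
                name="Scripted",
                logic_type="derived_concept",
                logic_path="Derived_Concept/Scripted",
                modality="script",
                spec=self.script_def(plugin="boom").model_dump(),
            )
        )
        run = engine.run_logic("Scripted")
        assert run.status == "failed"
        assert any("p2" in msg for msg in run.log)
        assert store.query_facts({"DERIVED:Scripted"}) == []

    def test_foreign_output_code_rejected(self, store):
        from cohortforge.errors import FactValidationError
        from cohortforge.plugins import PluginRegistry

        store.insert_facts([lab("p1", 100, "2020-01-01")])
        plugins = PluginRegistry()

        @plugins.register("mylast")
        def foreign(pid, chart):
            return [ObservationFact(pid, "DERIVED:Other", "2020-01-01", "flag")]

        with pytest.raises(FactValidationError, match="DERIVED:Other"):
            derived.compute_script(self.script_def(), store, plugins=plugins)


class TestMaterializeSemantics:
    def test_recompute_replaces_prior_output(self, store):
        store.insert_facts([lab("p1", 100, "2020-01-01"), lab("p1", 180, "2020-02-01")])
        defn = last_value_def()
        h = ConceptHierarchy()
        derived.materialize(defn, store, h)
        derived.materialize(defn, store, h)
        out = store.query_facts({defn.output_code})
        assert len(out) == 1  # delete-then-insert, not append

    def test_at_most_one_fact_per_patient(self, store):
        dataset = synth.generate(synth.SynthConfig(n_patients=100, seed=3))
        synth.load_direct(dataset, store)
        for defn in (last_value_def(), last_n_def()):
            out = derived.compute(defn, store)
            pids = [f.patient_id for f in out]
            assert len(pids) == len(set(pids))

    def test_derived_facts_use_ordinary_query_path(self, store):
        store.insert_facts([lab("p1", 180, "2020-01-01")])
        h = ConceptHierarchy()
        defn = last_value_def()
        derived.materialize(defn, store, h)
        # same query_facts path as any base concept, and queryable by path
        assert len(store.query_facts({defn.output_code}, (">", 150))) == 1
        assert h.expand(defn.concept_path) == {defn.output_code}
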