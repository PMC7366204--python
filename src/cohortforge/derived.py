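"""Derived-concept computation: the clinical inference layer.

Derived concepts materialise medical knowledge ("last HbA1c", "last two
consecutive serum glucose > 126") as ordinary observation facts coded
``DERIVED:<name>``, so complex cohort queries decompose into simple
single-concept filters. Because a derived concept may read another's
output, execution is planned as a topological order over the
"reads-output-of" graph; any cycle is detected up front and refused —
nothing executes.

Within a patient, "last" means chronologically last; facts sharing a
timestamp are ordered by insertion (stable), so recomputation on an
unchanged store is deterministic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx

from .errors import ConfigurationError, CycleError, FactValidationError
from .facts import ObservationFact
from .logics import DerivedConceptDef
from .ontology import ConceptHierarchy, expand_many
from .plugins import PluginRegistry
from .store import PatientStore, normalize_operator

_COMPARATORS = {
    ">": lambda v, t: v > t,
    "<": lambda v, t: v < t,
    ">=": lambda v, t: v >= t,
    "<=": lambda v, t: v <= t,
}


def _compare(value: float, comparator: str, threshold: float) -> bool:
    return _COMPARATORS[normalize_operator(comparator)](value, threshold)


def plan_execution(defs: Sequence[DerivedConceptDef]) -> list[DerivedConceptDef]:
    """Topologically order definitions so every def follows its sources.

    Edges come from source refs that resolve to another def's output code,
    name or concept path. Ties break by name (deterministic). Any cycle
    raises :class:`CycleError` naming the full cycle; nothing executes.
    """
    by_name = {d.name: d for d in defs}
    by_ref: dict[str, str] = {}
    for d in defs:
        by_ref[d.output_code] = d.name
        by_ref[d.name] = d.name
        by_ref[d.concept_path] = d.name

    graph = nx.DiGraph()
    graph.add_nodes_from(by_name)
    for d in defs:
        for ref in d.source_refs():
            dep = by_ref.get(ref)
            if dep is not None and dep != d.name:
                graph.add_edge(dep, d.name)

    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise CycleError([edge[0] for edge in cycle])

    order = list(nx.lexicographical_topological_sort(graph))
    return [by_name[name] for name in order]


def _patient_series(
    store: PatientStore, codes: Iterable[str]
) -> dict[str, list[ObservationFact]]:
    """Facts for the given codes grouped per patient, sorted by timestamp.

    The store returns insertion order; a stable sort on timestamp then
    leaves equal-time facts in insertion order, which defines "last".
    """
    groups: dict[str, list[ObservationFact]] = {}
    for fact in store.query_facts(codes):
        groups.setdefault(str(fact.patient_id), []).append(fact)
    for facts in groups.values():
        facts.sort(key=lambda f: f.start_datetime)
    return groups


def _resolve_source_codes(
    defn: DerivedConceptDef, hierarchy: ConceptHierarchy | None
) -> set[str]:
    codes = expand_many(hierarchy, [defn.source])
    if not codes:
        raise ConfigurationError(f"{defn.name}: source {defn.source!r} expands to no codes")
    return codes


def compute_last_value(
    defn: DerivedConceptDef,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
    log: list[str] | None = None,
) -> list[ObservationFact]:
    """Copy each patient's chronologically last numeric source value."""
    codes = _resolve_source_codes(defn, hierarchy)
    out = []
    for patient_id, facts in sorted(_patient_series(store, codes).items()):
        numeric = [f for f in facts if f.value_kind == "numeric"]
        if not numeric:
            if log is not None:
                log.append(
                    f"warning: patient {patient_id} has only non-numeric "
                    f"{sorted(codes)} facts; skipped"
                )
            continue
        last = numeric[-1]
        out.append(
            ObservationFact(
                patient_id=patient_id,
                concept_code=defn.output_code,
                start_datetime=last.start_datetime,
                value_kind="numeric",
                numeric_value=last.numeric_value,
                unit=last.unit,
                source_logic=defn.name,
            )
        )
    return out


def compute_last_n_consecutive_compare(
    defn: DerivedConceptDef,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
    log: list[str] | None = None,
) -> list[ObservationFact]:
    """Flag patients whose final n measurements all satisfy the comparison.

    Only the most recent ``n`` values are tested (not any adjacent n);
    patients with fewer than ``n`` source facts are never flagged.
    """
    codes = _resolve_source_codes(defn, hierarchy)
    out = []
    for patient_id, facts in sorted(_patient_series(store, codes).items()):
        numeric = [f for f in facts if f.value_kind == "numeric"]
        if len(numeric) < defn.n:
            continue
        tail = numeric[-defn.n :]
        if all(_compare(f.numeric_value, defn.comparator, defn.threshold) for f in tail):
            out.append(
                ObservationFact(
                    patient_id=patient_id,
                    concept_code=defn.output_code,
                    start_datetime=tail[-1].start_datetime,
                    value_kind="flag",
                    source_logic=defn.name,
                )
            )
    return out


def compute_any_code_present(
    defn: DerivedConceptDef,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
    log: list[str] | None = None,
) -> list[ObservationFact]:
    """Flag patients holding >=1 fact in the code set; earliest match dates it."""
    codes: set[str] = set()
    if defn.codes:
        codes |= expand_many(hierarchy, defn.codes)
    if defn.path:
        codes |= expand_many(hierarchy, [defn.path])
    if (defn.codes or defn.path) and not codes:
        raise ConfigurationError(f"{defn.name}: code set expands to nothing")
    if defn.code_prefix:
        # Prefix expansion is against observed store codes (plus catalogue
        # codes); an unmatched prefix simply flags nobody.
        codes |= set(store.distinct_codes(prefix=defn.code_prefix))
        if hierarchy is not None:
            codes |= {
                n.code
                for n in hierarchy.nodes.values()
                if n.code and n.code.startswith(defn.code_prefix)
            }
    if not codes:
        return []
    out = []
    for patient_id, facts in sorted(_patient_series(store, codes).items()):
        first = facts[0]
        out.append(
            ObservationFact(
                patient_id=patient_id,
                concept_code=defn.output_code,
                start_datetime=first.start_datetime,
                value_kind="flag",
                source_logic=defn.name,
            )
        )
    return out


def compute_compare_derived(
    defn: DerivedConceptDef,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
    log: list[str] | None = None,
) -> list[ObservationFact]:
    """Threshold a derived numeric value into a boolean flag per patient."""
    codes = _resolve_source_codes(defn, hierarchy)
    out = []
    for patient_id, facts in sorted(_patient_series(store, codes).items()):
        numeric = [f for f in facts if f.value_kind == "numeric"]
        if not numeric:
            continue
        last = numeric[-1]
        if _compare(last.numeric_value, defn.comparator, defn.threshold):
            out.append(
                ObservationFact(
                    patient_id=patient_id,
                    concept_code=defn.output_code,
                    start_datetime=last.start_datetime,
                    value_kind="flag",
                    source_logic=defn.name,
                )
            )
    return out


def compute_script(
    defn: DerivedConceptDef,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
    plugins: PluginRegistry | None = None,
    log: list[str] | None = None,
) -> list[ObservationFact]:
    """Run a plugin once per patient over the sorted chart.

    The plugin must return well-formed facts bearing the definition's
    output code; a foreign code or an exception fails the whole run and
    nothing is inserted.
    """
    if plugins is None:
        raise ConfigurationError(f"{defn.name}: no plugin registry supplied")
    plugin = plugins.get(defn.plugin)
    out = []
    for patient_id in store.patient_ids():
        chart = store.patient_chart(patient_id)
        try:
            produced = list(plugin(patient_id, chart) or [])
        except Exception as exc:
            raise ConfigurationError(
                f"{defn.name}: plugin {defn.plugin!r} failed for patient "
                f"{patient_id}: {exc}"
            ) from exc
        for fact in produced:
            if fact.concept_code != defn.output_code:
                raise FactValidationError(
                    "concept_code",
                    f"plugin {defn.plugin!r} emitted foreign code "
                    f"{fact.concept_code!r} (expected {defn.output_code!r})",
                )
            fact.source_logic = defn.name
            fact.validate()
            out.append(fact)
    return out


_DISPATCH = {
    "last_value": compute_last_value,
    "last_n_consecutive_compare": compute_last_n_consecutive_compare,
    "any_code_present": compute_any_code_present,
    "compare_derived": compute_compare_derived,
}


def compute(
    defn: DerivedConceptDef,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
    plugins: PluginRegistry | None = None,
    log: list[str] | None = None,
) -> list[ObservationFact]:
    """Dispatch to the operator implementation; facts are not yet inserted."""
    if defn.operator == "script":
        return compute_script(defn, store, hierarchy, plugins, log)
    return _DISPATCH[defn.operator](defn, store, hierarchy, log)


def materialize(
    defn: DerivedConceptDef,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
    plugins: PluginRegistry | None = None,
    log: list[str] | None = None,
) -> int:
    """Compute and store a definition's facts, replacing any prior output.

    Delete-then-insert keyed by ``source_logic`` makes reruns re-entrant:
    recomputing on an unchanged store yields an identical fact set. The
    derived concept is auto-registered in the ontology under its
    ``concept_path`` so it is queryable by path like any other concept.
    """
    facts = compute(defn, store, hierarchy, plugins, log)
    removed = store.delete_facts(defn.name)
    if log is not None and removed:
        log.append(f"replaced {removed} prior {defn.output_code} facts")
    inserted = store.insert_facts(facts)
    if hierarchy is not None:
        hierarchy.add_node(defn.concept_path, code=defn.output_code, name=defn.name)
    return inserted
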