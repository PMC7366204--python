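"""Cohort query trees: sibling nodes OR, child nodes AND.

A query is a forest of filter nodes. Each node filters on one concept
(an ontology path or explicit codes — derived ``DERIVED:`` codes work
exactly like base codes) with an operator (``>``, ``<``, ``>=``, ``<=``,
``=``, ``exists``) and an optional closed time window. A patient matches
a node if at least one of their facts passes the filter.

Evaluation semantics: ``cumulative(node) = matched(node) ∩
cumulative(parent)`` (roots: cumulative = matched), and the final cohort
is the union of the cumulative sets of the *leaves* — i.e. each
root-to-leaf path is a conjunction, the paths are OR-ed. Counts are
distinct patients, so along any root-to-descendant path they are
non-increasing: the attrition funnel the flow diagram renders.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterator, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import EvaluationError, ExportError, NotFoundError
from .facts import ObservationFact, format_datetime, parse_datetime
from .ontology import ConceptHierarchy, expand_many
from .store import PatientStore, normalize_operator


class QueryNode(BaseModel):
    node_id: str
    label: Optional[str] = None
    concept: Optional[str] = None  # ontology path or namespaced code
    codes: Optional[list[str]] = None  # explicit code set (alternative to concept)
    operator: str = "exists"
    threshold: Optional[float] = None
    window: Optional[tuple[str, str]] = None
    children: list["QueryNode"] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        op = normalize_operator(self.operator)
        if op == "exists" and self.threshold is not None:
            raise ValueError(f"node {self.node_id}: exists nodes carry no threshold")
        if op != "exists" and self.threshold is None:
            raise ValueError(f"node {self.node_id}: operator {op!r} needs a threshold")
        if not (self.concept or self.codes):
            raise ValueError(f"node {self.node_id}: needs a concept ref or code set")
        if self.window is not None:
            lo, hi = (parse_datetime(w) for w in self.window)
            if lo > hi:
                raise ValueError(f"node {self.node_id}: window endpoints out of order")
        return self

    def display_label(self) -> str:
        return self.label or self.node_id


class CohortQuery(BaseModel):
    name: Optional[str] = None
    roots: list[QueryNode] = Field(min_length=1)

    @model_validator(mode="after")
    def _unique_ids(self):
        seen = set()
        for node, _ in self.walk():
            if node.node_id in seen:
                raise ValueError(f"duplicate node_id {node.node_id!r}")
            seen.add(node.node_id)
        return self

    def walk(self) -> Iterator[tuple[QueryNode, Optional[QueryNode]]]:
        """Yield (node, parent) pairs in depth-first pre-order."""
        stack = [(root, None) for root in reversed(self.roots)]
        while stack:
            node, parent = stack.pop()
            yield node, parent
            for child in reversed(node.children):
                stack.append((child, node))

    def node(self, node_id: str) -> QueryNode:
        for node, _ in self.walk():
            if node.node_id == node_id:
                return node
        raise NotFoundError(f"no query node {node_id!r}")


@dataclasses.dataclass
class NodeResult:
    node_id: str
    matched: set[str]
    cumulative: set[str]

    @property
    def count(self) -> int:
        return len(self.cumulative)


@dataclasses.dataclass
class QueryEvaluation:
    """Evaluation output: per-node results plus the final cohort."""

    query: CohortQuery
    results: dict[str, NodeResult]
    cohort: set[str]
    _store: PatientStore
    _hierarchy: Optional[ConceptHierarchy]

    def count(self, node_id: str) -> int:
        return self.results[node_id].count

    def drill_down(self, node_id: str) -> pd.DataFrame:
        """Patient listing for a node with the facts satisfying its filter.

        One row per (patient, supporting fact), ordered by patient_id;
        every listed fact re-satisfies the node predicate.
        """
        if node_id not in self.results:
            raise NotFoundError(f"no evaluated node {node_id!r}")
        node = self.query.node(node_id)
        cumulative = self.results[node_id].cumulative
        rows = []
        for fact in _node_facts(node, self._store, self._hierarchy):
            pid = str(fact.patient_id)
            if pid not in cumulative:
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "concept_code": fact.concept_code,
                    "start_datetime": format_datetime(fact.start_datetime),
                    "value_kind": fact.value_kind,
                    "numeric_value": fact.numeric_value,
                    "unit": fact.unit,
                    "text_value": fact.text_value,
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "concept_code",
                "start_datetime",
                "value_kind",
                "numeric_value",
                "unit",
                "text_value",
            ],
        )
        return frame.sort_values(
            ["patient_id", "start_datetime"], kind="stable"
        ).reset_index(drop=True)


def _node_codes(node: QueryNode, hierarchy: ConceptHierarchy | None) -> set[str]:
    refs = list(node.codes or [])
    if node.concept:
        refs.append(node.concept)
    try:
        codes = expand_many(hierarchy, refs)
    except NotFoundError as exc:
        raise EvaluationError(f"node {node.node_id}: {exc}") from exc
    if not codes:
        raise EvaluationError(f"node {node.node_id}: concept ref expands to no codes")
    return codes


def _node_facts(
    node: QueryNode, store: PatientStore, hierarchy: ConceptHierarchy | None
) -> list[ObservationFact]:
    codes = _node_codes(node, hierarchy)
    op = normalize_operator(node.operator)
    predicate = (op,) if op == "exists" else (op, node.threshold)
    return store.query_facts(codes, value_predicate=predicate, window=node.window)


def evaluate(
    query: CohortQuery,
    store: PatientStore,
    hierarchy: ConceptHierarchy | None = None,
) -> QueryEvaluation:
    """Evaluate a query tree; returns per-node attrition sets and the cohort.

    All concept refs are resolved up front so an unresolvable node fails
    the whole evaluation with no partial results.
    """
    node_order = list(query.walk())
    for node, _ in node_order:
        _node_codes(node, hierarchy)  # fail fast before computing anything

    results: dict[str, NodeResult] = {}
    cohort: set[str] = set()
    for node, parent in node_order:
        matched = {str(f.patient_id) for f in _node_facts(node, store, hierarchy)}
        if parent is None:
            cumulative = set(matched)
        else:
            cumulative = matched & results[parent.node_id].cumulative
        results[node.node_id] = NodeResult(node.node_id, matched, cumulative)
        if not node.children:  # only leaves terminate a conjunction path
            cohort |= cumulative
    return QueryEvaluation(
        query=query, results=results, cohort=cohort, _store=store, _hierarchy=hierarchy
    )


def load_query_yaml(source) -> CohortQuery:
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        try:
            with open(source, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(source)
    return CohortQuery.model_validate(data)


# -- flow-diagram export ----------------------------------------------------


def _check_complete(evaluation: QueryEvaluation) -> list[tuple[QueryNode, Optional[QueryNode]]]:
    nodes = list(evaluation.query.walk())
    query_ids = {n.node_id for n, _ in nodes}
    if query_ids != set(evaluation.results):
        raise ExportError(
            f"results cover {sorted(evaluation.results)} but query has {sorted(query_ids)}"
        )
    return nodes


def export_flow(evaluation: QueryEvaluation, format: str = "json") -> str:
    """Render the attrition flow diagram as json, dot or mermaid text.

    Node and edge order is sorted by node_id, so output is text-stable
    for snapshot comparison.
    """
    pairs = _check_complete(evaluation)
    nodes = sorted(
        (
            {
                "id": n.node_id,
                "label": n.display_label(),
                "count": evaluation.results[n.node_id].count,
            }
            for n, _ in pairs
        ),
        key=lambda d: d["id"],
    )
    edges = sorted(
        (
            {"from": parent.node_id, "to": n.node_id}
            for n, parent in pairs
            if parent is not None
        ),
        key=lambda d: (d["from"], d["to"]),
    )
    cohort_size = len(evaluation.cohort)

    if format == "json":
        return json.dumps(
            {"nodes": nodes, "edges": edges, "cohort_size": cohort_size}, indent=2
        )
    if format == "dot":
        lines = ["digraph cohort {", f'  label="cohort_size={cohort_size}";']
        for n in nodes:
            lines.append(f'  "{n["id"]}" [label="{n["label"]}\\n(n={n["count"]})"];')
        for e in edges:
            lines.append(f'  "{e["from"]}" -> "{e["to"]}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "mermaid":
        lines = ["graph TD", f"  %% cohort_size: {cohort_size}"]
        for n in nodes:
            lines.append(f'  {n["id"]}["{n["label"]} (n={n["count"]})"]')
        for e in edges:
            lines.append(f'  {e["from"]} --> {e["to"]}')
        return "\n".join(lines) + "\n"
    raise ExportError(f"unknown flow format {format!r}")
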