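"""Independent brute-force oracles used across the test suite.

Everything here works on plain fact lists with linear scans and explicit
set algebra — no store SQL, no hierarchy indexes, no query-tree
machinery — so it stays an independent check on the implementation.
"""

from __future__ import annotations

import random
from datetime import datetime, timedelta

from cohortforge.facts import ObservationFact, parse_datetime
from cohortforge.query import CohortQuery, QueryNode

_OPS = {
    ">": lambda v, t: v > t,
    "<": lambda v, t: v < t,
    ">=": lambda v, t: v >= t,
    "<=": lambda v, t: v <= t,
    "≥": lambda v, t: v >= t,
    "≤": lambda v, t: v <= t,
    "=": lambda v, t: v == t,
}


def fact_passes(fact: ObservationFact, codes, operator, threshold, window) -> bool:
    if fact.concept_code not in codes:
        return False
    when = parse_datetime(fact.start_datetime)
    if window is not None:
        lo, hi = (parse_datetime(w) for w in window)
        if not (lo <= when <= hi):
            return False
    if operator == "exists":
        return True
    if fact.value_kind != "numeric":
        return False
    return _OPS[operator](fact.numeric_value, threshold)


def scan_facts(facts, codes, operator="exists", threshold=None, window=None):
    """Linear-scan equivalent of PatientStore.query_facts."""
    return [f for f in facts if fact_passes(f, set(codes), operator, threshold, window)]


def node_codes(node: QueryNode) -> set[str]:
    codes = set(node.codes or [])
    if node.concept:
        codes.add(node.concept)
    return codes


def node_match_set(node: QueryNode, facts) -> set[str]:
    codes = node_codes(node)
    return {
        str(f.patient_id)
        for f in facts
        if fact_passes(f, codes, node.operator, node.threshold, node.window)
    }


def dnf_evaluate(query: CohortQuery, facts):
    """Brute-force DNF evaluation of a query tree over a fact list.

    For every leaf, intersect the match sets of all filters on its
    root-path; the cohort is the union over leaves. Also returns per-node
    matched and cumulative sets computed the same way.
    """
    matched: dict[str, set[str]] = {}
    cumulative: dict[str, set[str]] = {}
    cohort: set[str] = set()

    def visit(node: QueryNode, path_sets: list[set[str]]):
        own = node_match_set(node, facts)
        matched[node.node_id] = own
        cum = set(own)
        for s in path_sets:
            cum &= s
        cumulative[node.node_id] = cum
        if not node.children:
            cohort.update(cum)
        for child in node.children:
            visit(child, path_sets + [own])

    for root in query.roots:
        visit(root, [])
    return matched, cumulative, cohort


# -- random instance generators --------------------------------------------


CODE_POOL = [
    "LOINC:1000-1",
    "LOINC:2000-2",
    "LOINC:3000-3",
    "ICD9:100.0",
    "ICD9:200.0",
    "DERIVED:FlagA",
]

T0 = datetime(2020, 1, 1)


def random_facts(rng: random.Random, n_patients: int, facts_per_patient=(5, 20)):
    facts = []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        for _ in range(rng.randint(*facts_per_patient)):
            code = rng.choice(CODE_POOL)
            when = T0 + timedelta(hours=rng.randrange(365 * 24))
            if code.startswith(("ICD9", "DERIVED")):
                facts.append(
                    ObservationFact(pid, code, when, value_kind="flag")
                )
            else:
                facts.append(
                    ObservationFact(
                        pid,
                        code,
                        when,
                        value_kind="numeric",
                        numeric_value=round(rng.uniform(0, 200), 1),
                    )
                )
    return facts


def random_query(rng: random.Random, max_depth=4, max_branch=3) -> CohortQuery:
    counter = [0]

    def make_node(depth: int) -> QueryNode:
        counter[0] += 1
        node_id = f"n{counter[0]}"
        codes = rng.sample(CODE_POOL, rng.randint(1, 2))
        numeric_ok = all(c.startswith("LOINC") for c in codes)
        operator = rng.choice([">", "<", ">=", "<="]) if numeric_ok and rng.random() < 0.7 else "exists"
        threshold = round(rng.uniform(0, 200), 1) if operator != "exists" else None
        window = None
        if rng.random() < 0.3:
            lo = T0 + timedelta(days=rng.randrange(200))
            hi = lo + timedelta(days=rng.randrange(30, 200))
            window = (lo.isoformat(), hi.isoformat())
        children = []
        if depth < max_depth and rng.random() < 0.55:
            children = [make_node(depth + 1) for _ in range(rng.randint(1, max_branch))]
        return QueryNode(
            node_id=node_id,
            codes=codes,
            operator=operator,
            threshold=threshold,
            window=window,
            children=children,
        )

    roots = [make_node(2) for _ in range(rng.randint(1, max_branch))]
    return CohortQuery(roots=roots)
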