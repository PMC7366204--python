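# Methods

## The model

`cohortforge` treats cohort identification as three composable layers
over an i2b2-style star schema.

**Facts.** The unit of data is the observation fact: a patient
identifier, a namespaced concept code (`SYSTEM:code`), a timezone-naive
timestamp, and exactly one value payload matching its kind (numeric
with unit, text, or a bare flag). Namespacing the codes (`ICD9:`,
`LOINC:`, `LOCAL:`, `DERIVED:`) lets several coding systems and locally
derived concepts share one fact table without collision; i2b2 itself
achieves the same with per-source code prefixes. Timestamps are stored
as whole-second ISO-8601 strings so lexicographic and chronological
order coincide inside the SQLite backing file; insertion order (an
AUTOINCREMENT key) is the documented tie-break everywhere a "last"
value must be chosen. Appending is atomic per batch: every fact in a
batch is validated before any row is written.

**Concept hierarchy.** Concepts form a forest addressed by
`/`-separated paths; leaves carry codes, folders do not. Expanding a
path (or a code) collects the codes of the node and all descendants, so
querying a folder implicitly matches everything under it. Local codes
are mapped by attaching them as children of *every* node bearing their
standard code — the standard concept then transparently expands to its
local variants. When a standard code appears at several paths the
mapping is applied under each occurrence; this is an interpretation
(the alternative, first-occurrence-only, would make expansion depend on
load order). The interchange format is a three-column TSV with `/`
paths; a writer option emits the i2b2-native `\` dialect.

**Derived concepts.** A derived definition reads base (or other
derived) facts and emits at most one fact per patient under
`DERIVED:<name>`:

* `last_value` — copy value and timestamp of the chronologically last
  numeric source fact;
* `last_n_consecutive_compare` — flag iff the patient has ≥ n source
  values and the **final** n all satisfy `comparator threshold`. "Last
  two consecutive glucose > 126" is read as a property of the most
  recent pair, not of any adjacent pair; the test suite pins this with
  a case where an earlier adjacent pair passes but the final pair does
  not;
* `any_code_present` — flag on the earliest fact whose code is in the
  expansion of a path, an explicit code set, or a code prefix;
* `compare_derived` — threshold another derived numeric value into a
  flag;
* `script` — a registered plugin called per patient with the sorted
  chart (the hook for risk scores or trained models; none ship).

Execution is planned as a lexicographic topological sort (ties broken
by name, so plans are deterministic) over the "reads-output-of" graph;
a cycle aborts the whole plan before anything runs. Recomputation is
delete-then-insert keyed by the producing definition, so pipelines are
re-entrant and recomputing on an unchanged store is a fixed point.
Derived facts carry no encounter linkage — they summarise a patient,
not a visit. Thresholds are user parameters throughout; the packaged
diabetes example uses > 126 mg/dL (glucose pair) and > 6.4 % (HbA1c),
with strict inequality, so values exactly at the boundary are excluded.

**Queries.** Sibling nodes OR, children AND:
`cumulative(v) = matched(v) ∩ cumulative(parent)`, cohort =
⋃ cumulative(leaf). Only leaves terminate a conjunction path — this is
the one reading of OR-siblings/AND-children that stays consistent for
arbitrary trees. Counts are distinct patients, hence non-increasing
along any root-to-descendant path (attrition monotonicity), and raising
a `>` threshold can only shrink a node's subtree counts. Time windows
are closed on both ends. Negation/exclusion is deliberately out of
scope: complex criteria are expected to be decomposed into positive
filters, optionally via derived concepts.

## The orchestrator

A local, synchronous executor replaces managed cloud pipelines while
keeping the same contract: register a Logic, trigger it (manually, or
by polling `run_due()` for schedule-tagged Logics — no daemon), and get
back a run record with status, row counts, watermark and log. SQL
imports fetch in batches of `batch_count`; each batch is atomic, and a
malformed row fails its batch and the run while keeping earlier batches
(restart-friendly for large loads). Incremental loading uses a
per-Logic watermark persisted in the store: only rows with watermark
strictly greater than the stored mark are imported, and the mark
advances to the maximum successfully written. Rows that share the
boundary watermark value are the source's responsibility — a documented
limitation; the packaged staging tables avoid it with a monotone
integer `row_id`. The i2b2-cdi flat-file dialect (defined by this
package: tagged `C`/`M`/`F` lines for concepts, mappings, facts) loads
concept metadata before facts and validates every fact against the
declared-plus-existing catalogue before mutating anything, making a
file import atomic.

## The synthetic generator

The generator emulates what the packaged evaluation needs from a real
critical-care extract: ICD-9-coded diagnoses and LOINC-coded numeric
lab series (serum glucose 2345-7, HbA1c 4548-4) for `n_patients`
patients over 2008–2012, staged in MIMIC-III-shaped tables. A planted
fraction (`phenotype_prevalence`, default 0.3) are diabetes cases; each
case receives a uniformly random non-empty subset of the three cohort
criteria, and value draws are truncated so membership is crisp: case
final HbA1c in (6.5, 12.0] vs control [4.0, 6.4]; case final glucose
pair in (126, 300] vs a control-final value in [60, 126]; diagnosis
codes for criterion members come from the ICD-9 250.x pool, all other
codes from a non-250.x pool. Counts per patient default to 3–8 glucose,
1–4 HbA1c and 1–4 diagnoses — enough temporal depth for "last n"
semantics without bulk. `fuzzy=True` additionally plants finals exactly
at 6.4 / 126.0 in a quarter of eligible controls to exercise the strict
`>` boundary. Values are quantised to one decimal and timestamps to a
strictly increasing integer-hour grid per patient per concept, so a
seed determines the dataset byte-for-byte (`random.Random`, stable
across platforms).

What the generator does **not** model: visit structure beyond one
encounter per patient, inter-lab correlation, demographic effects,
missingness, coding noise, or borderline patients outside fuzzy mode.
Passing tests therefore demonstrate that the machinery is exact on
separable data — that imports conserve rows, derived operators
implement their definitions, and query evaluation equals its set
semantics — not that the three criteria are clinically accurate on
noisy real-world records.

## Verification strategy and problem sizes

Every operation with non-obvious semantics is checked against an
independent brute-force oracle: linear-scan filtering for the store,
recursive tree walks for hierarchy expansion, per-patient
sort-slice-compare for derived operators, and full DNF evaluation
(intersect every root-path, union over leaves) for query trees. The
end-to-end check generates 1,000 patients at 30 % prevalence, pushes
them through staging tables, the eight-Logic catalogue and the
three-criterion query, and requires exact ground-truth recovery (zero
false positives and negatives). Oracle comparisons use 200 random query
trees (≤ 4 levels, ≤ 3 branching) over stores of 50–300 patients and
500-patient derived-operator runs — sizes chosen so the whole suite and
the acceptance script each complete in seconds while still exercising
multi-batch imports and non-trivial tree shapes.

## Known limitations

* Provider identifiers are carried on facts but not filterable.
* No negation/exclusion operator in query trees.
* Watermark ties at the boundary value can skip or re-read rows if the
  source's watermark column is not strictly monotone.
* The cdi dialect is this package's definition; external i2b2-cdi files
  may need translation.
* Scheduling is a tag plus an explicit `run_due()` poll; there is no
  background trigger machinery.
* Importing a real MIMIC-III instance works through the same SQL-import
  path as the staged synthetic tables but requires credentialed access
  and is not exercised here.
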