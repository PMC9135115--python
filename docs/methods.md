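# Methods

## The problem

A *feasibility query* asks a network of hospitals a single question: how
many patients satisfy this combination of eligibility criteria?  The
answer — one integer per site — tells a study planner whether a trial or
data-use project is feasible before any data-sharing agreement exists.
`feasquery` models the whole path of such a query at desk scale: the
formal query document, its translation into two executable query
languages, local execution against a FHIR R4 store, privacy obfuscation
of the count, and collection across a simulated multi-site network.

## Query model

A Structured Query has inclusion criteria in conjunctive normal form
(an AND of OR-groups) and exclusion criteria in disjunctive normal form
(an OR of AND-groups).  A patient matches iff

    [∀ g ∈ inclusion: ∃ c ∈ g: sat(p, c)]  ∧  ¬[∃ g ∈ exclusion: ∀ c ∈ g: sat(p, c)]

Each criterion carries one or more term codes — (code system, code)
pairs such as ICD-10 diagnoses, OPS procedures, LOINC laboratory codes,
or an administrative-gender value — plus an optional value filter
(coded value, quantity comparator, or inclusive quantity range in a UCUM
unit) and an optional calendar-date window (inclusive at both bounds,
day precision).  Term-code equality ignores display text.

The comparator set is `gt ge lt le eq`; `ne` is deliberately excluded
because a negated token search is not reliably expressible in FHIR
Search, and negative eligibility logic belongs in the exclusion groups,
where it is handled by set difference.

The JSON dialect is strict: unknown fields are rejected with the field
path named, so a drifting producer fails loudly instead of silently
changing cohort semantics.  Serialization is canonical (fixed key
order), so `parse ∘ serialize` is the identity and output is
byte-identical across runs.  A JSON Schema for the dialect ships in
`src/feasquery/schema/`.

`evaluate_reference` is a deliberately naive per-patient boolean
evaluator over precomputed truth assignments.  It is the semantic
oracle: every executable path must agree with it, and the test suite
enforces this on randomized instances.

## Terminology-driven translation

Two configuration files drive translation.  The *terminology tree* (a
JSON forest) captures the concept hierarchy; a selected parent code
expands to itself plus all descendants in depth-first pre-order.  The
parent itself is always included, since real data may be coded at the
parent level.  The *mapping file* names, per concept, the FHIR resource
type and search parameters used to find it.  A code missing from the
tree simply expands to itself; a code missing from the mapping raises
`MappingNotFound` at translation time — a criterion is never silently
dropped, because a dropped criterion would silently inflate a cohort.

### FHIR Search path

FHIR Search cannot express inter-criterion logic, so each criterion
becomes a bundle of one or more atomic queries (`Type?param=value&…`)
and the logic is recovered afterwards by set algebra over patient
identifiers.  Rendering rules:

* token values are `system|code` (collision-safe); mappings may opt into
  bare-code form for value-set style parameters (`Patient?gender=female`);
* quantities render as `<prefix><value>|<ucum-system>|<unit>`; ranges
  become a `ge` and an `le` parameter;
* date windows become `ge`/`le` parameters on the mapping's date
  parameter;
* parameter order is fixed (code, value, time) and each token is
  percent-encoded, so rendering is deterministic and losslessly
  parseable.

Expanded code lists are chunked at 200 codes per query by default — a
URL-length safety margin, configurable — and the executor unions the
chunk results, so results are invariant to chunk size.

### CQL path

The whole query also renders as a single CQL library (`library` header,
one `codesystem` declaration per distinct system in first-use order,
`context Patient`, one `define` per criterion, and
`define InInitialPopulation` combining them).  CQL *execution* is out of
scope — running CQL is the job of a CQL-capable FHIR server — so
correctness of the generated text is established structurally: an
independent checker validates bracket balance and alias
declaration-before-use, and the boolean skeleton of
`InInitialPopulation` is parsed and enumerated over all truth
assignments (≤ 12 criteria), which must reproduce the reference
evaluator's CNF/DNF contract exactly.

## Local FHIR store and executor

The in-memory store supports the four resource types the benchmark
design uses (Patient, Condition, Procedure, Observation) with NDJSON and
collection-Bundle I/O, token indexes on `code`/`gender`, and exactly the
search subset the translator emits.  Any other parameter raises
`UnsupportedSearch`: silently ignoring a parameter would return a
superset and inflate counts.  Deliberate simplifications, all
documented divergences from a full server: quantity `eq` is exact
decimal comparison (no significant-digit rounding), dates compare at day
precision with inclusive bounds, and Condition time restrictions map to
`recorded-date`.

The executor runs every atomic query — no short-circuiting, no
reordering by selectivity — and combines patient-ID sets: union within a
criterion bundle and within an inclusion OR-group, intersection across
inclusion groups and within an exclusion AND-group, union across
exclusion groups, then set difference.  The worst-case discipline makes
the `resourcesProcessed` tally (total resources returned over all atomic
queries) deterministic and exactly predictable, which is what the
benchmark design measures.  A selectivity-ordering optimizer would
change only speed, not results, and is intentionally absent.

## Privacy

Each site rounds its exact count to the nearest multiple of 10 before
reporting (ties round up; a true zero stays zero).  Counts 1–4 therefore
report as 0 — a small-count disclosure trade-off accepted by design.
The rounding is monotone, always within 5 of the truth, and the network
layer is built so that only `ObfuscatedCount` values can appear in site
results and reports; a test asserts the exact count never appears in any
serialized boundary object.

## Site network

The broker/site simulation is in-process but protocol-faithful: sites
poll the broker and pull the query envelope (hospitals do not accept
inbound connections), the envelope carries both representations
(Structured Query JSON and CQL text) so each site chooses its path
locally, failures are isolated per site, and every broadcast returns
exactly one result per registered site ordered by site id.  The `cql`
execution path is carried in the envelope but rejected at configuration
time, since no CQL engine is bundled.  Timeouts are wall-clock per site
against the configured budget.

## Synthetic benchmark data

The generator plants cohorts of exactly known sizes: every member of a
cohort carries one matching gender, one Condition, one Procedure, and
one Observation with codes unique to that cohort, so each benchmark
query has an exactly predictable answer and the 4-criterion AND query
processes exactly 4 × N resources.  Built-in profiles:

| profile  | cohorts                         | background                     |
|----------|---------------------------------|--------------------------------|
| small    | 1 000 / 10 000 / 100 000        | none                           |
| bg-small | same                            | 413 375 Conditions (8 593 codes), 270 505 Procedures (6 429 codes), 4 907 600 Observations (1 798 codes) |
| bg-large | + 1 000 000                     | same                           |

Design choices where the design was genuinely open:

* **Patient-level criterion.** Each cohort gets a distinct
  administrative-gender value (female on the 100 000 cohort, which also
  carries the worked-example codes C50.1 / 5-787.ex / 55782-7), so the
  patient criterion matches exactly its cohort — required for the
  4 × N resources-processed arithmetic.  This caps the generator at four
  cohorts (one per gender value), which covers every built-in profile.
* **Background distribution.** Only totals and unique-code counts are
  specified for background data; the underlying hospital code-frequency
  distribution is not public.  Totals are split over the codes as evenly
  as possible (⌊n/k⌋ or ⌈n/k⌉ per code) and attached round-robin to
  existing patients — background adds resources, never patients.
  Background codes are namespaced (`BG-*`) and provably disjoint from
  cohort codes.
* **Dates and values.** Clinical dates are uniform over a fixed 5-year
  window (2018-01-01 … 2022-12-31); background observation values
  uniform in 0.1–500 mg/dL.  These exist only so date and value filters
  have something to bite on; no benchmark query depends on them.
* **No-match query.** The `0` query ANDs four mapped codes absent from
  the data; its patient criterion uses an unplanted gender value when
  one exists (e.g. `unknown` in the 3-cohort profiles) and a synthetic
  token otherwise.

Scaling: a profile accepts an exact rational factor (e.g. `1/1000`).
Cohort sizes and background totals must scale to integers (anything else
is an error naming the count); unique-code counts are shape rather than
size and shrink as ⌈k·s⌉ with a floor of one code.  At scale `s` every
planted query answer scales by exactly `s`, which the tests verify.

Determinism: all randomness comes from per-stream `random.Random`
instances seeded from `(seed, stream-label)`, so regeneration is
byte-identical for a given seed and independent of which resource types
are materialized.

### What the generator does and does not emulate

It reproduces the benchmark geometry exactly — counts, code
cardinalities, planted answers — which is what the executor and the
acceptance surface measure.  It does not attempt clinical realism: no
profile/slicing conformance, no comorbidity structure, no realistic
code-frequency skew, one resource per criterion per member.  Passing
tests therefore demonstrate correctness of query semantics and
accounting, not performance on, or robustness to, real hospital data.

## Problem sizes used in the checks

The test suite and the reproduction script run the `small` profile at
full scale (111 000 patients, 444 000 resources) and stream-count the
background component (≈ 5.6 M resources) without materializing it; the
randomized equivalence checks use 200 instances of small random stores
(3–12 patients) where the brute-force oracle is exact and cheap.  The
million-patient `bg-large` profile is generated only in streamed form by
tests; materializing it is supported but unnecessary for any shipped
check.

## Known limitations

* No HTTP transport, paging, `_count`, sorting, or FHIR validation; the
  store answers only the emitted search subset.
* CQL text is generated but never executed; its semantics are vouched
  for by the skeleton-equivalence check only.
* Patient identity is per-site resource id; no cross-site record
  linkage.
* The obfuscation is rounding, not differential privacy; repeated
  correlated queries can still leak under an active adversary.
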