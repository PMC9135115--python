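# feasquery

A desk-scale, self-contained toolkit for **federated cohort feasibility
querying** over FHIR R4 data — for clinical-research informaticians who
want to study, test, or extend the mechanics of a distributed
feasibility platform without standing up FHIR servers, brokers, and
middleware.

A feasibility query asks each hospital in a network one question: *how
many of your patients satisfy this criteria combination?*  `feasquery`
implements the full path of that question:

* a **Structured Query** model — inclusion criteria in conjunctive
  normal form, exclusion criteria in disjunctive normal form; a patient
  matches iff

  ```
  (∀ inclusion group ∃ satisfied criterion) ∧ ¬(∃ exclusion group ∀ criteria satisfied)
  ```

* **terminology-driven translation**: a terminology tree expands each
  code to all its subtypes (E11 → E11.0 … E11.9), and a mapping file
  names the FHIR resource type and search parameters per concept;
* a **FHIR Search decomposition path**: the query becomes atomic
  `Type?param=value` requests whose patient-ID sets are combined by set
  algebra (union within OR-groups, intersection across AND-groups, set
  difference for exclusions);
* a **CQL path**: the same query rendered as a single CQL library
  defining `InInitialPopulation` (text generation; execution is a FHIR
  server's job);
* an in-memory **FHIR store** (Patient, Condition, Procedure,
  Observation; NDJSON / Bundle I/O) that evaluates the emitted search
  subset;
* **privacy obfuscation** — a site's exact count is rounded to the
  nearest 10 before it leaves (0 stays 0);
* a **pull-based broker/site simulation** distributing a query envelope
  that carries both representations;
* a **synthetic-data generator** that plants cohorts of exactly known
  sizes plus configurable background load, so every benchmark query has
  an exactly predictable answer.

## Worked example

Generate a 1/1000-scale benchmark data set (111 patients, 444
resources, plus terminology, mapping, and the benchmark queries):

```sh
feasquery gen --profile small --scale 1/1000 --seed 1 --out demo/
```

Run the planted single-criterion query for the 100 000-cohort (100
members at this scale) against it:

```sh
feasquery run --query demo/queries/100000-1.json \
              --tree demo/term-tree.json --mapping demo/mapping.json \
              --data demo/
```

```json
{
 "obfuscatedCount": 100,
 "resourcesProcessed": 100
}
```

The cohort has exactly 100 members, each with one matching Condition:
100 patients found, 100 resources processed, and 100 is already a
multiple of 10 so obfuscation leaves it unchanged.  The same query via
`feasquery run --network …` fans out to N simulated sites and sums their
obfuscated counts.

Translating the 4-criterion AND query instead:

```sh
feasquery translate --query demo/queries/1000-all.json --to fhir-search \
                    --tree demo/term-tree.json --mapping demo/mapping.json
```

yields one atomic query per criterion —
`Patient?gender=male`, `Condition?code=…%7CCOH0-COND`, … — whose result
sets the executor intersects; `--to cql` emits the equivalent single CQL
library.

The same flows are available as a library:

```python
from feasquery import count_query, obfuscate
from feasquery.synthetic import benchmark_queries, generate, get_profile, terminology_for

profile = get_profile("small", "1/1000")
store = generate(profile, seed=1)
tree, mapping = terminology_for(profile)
label, query = benchmark_queries(profile)[2]          # "1000-all"
result = count_query(query, store, tree, mapping)
print(label, result.patient_count, result.resources_processed)   # 1000-all 1 4
print(obfuscate(result.patient_count).value)                     # 0
```

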