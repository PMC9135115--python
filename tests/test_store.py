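"""FHIR resource store: loading, indexing, and the search-subset evaluator."""

import json
import random
from decimal import Decimal

import pytest

from feasquery.fhir_search import AtomicQuery
from feasquery.query_model import Criterion, TermCode
from feasquery.store import ResourceStore, StoreError, UnsupportedSearch, patient_ids

from conftest import ICD, LOINC, UCUM, random_store


def atomic(resource_type: str, *params: tuple[str, str]) -> AtomicQuery:
    c = Criterion(term_codes=[TermCode(system="urn:test", code="x")])
    return AtomicQuery(resource_type, tuple(params), c)


def patient(pid, gender="female"):
    return {"resourceType": "Patient", "id": pid, "gender": gender, "birthDate": "1980-05-01"}


def condition(rid, pid, code, date="2020-06-01"):
    return {"resourceType": "Condition", "id": rid,
            "code": {"coding": [{"system": ICD, "code": code}]},
            "subject": {"reference": f"Patient/{pid}"}, "recordedDate": date}


def observation(rid, pid, code, value, date="2020-06-01"):
    return {"resourceType": "Observation", "id": rid,
            "code": {"coding": [{"system": LOINC, "code": code}]},
            "subject": {"reference": f"Patient/{pid}"},
            "valueQuantity": {"value": value, "unit": "mg/dL", "system": UCUM},
            "effectiveDateTime": date}


class TestLoading:
    def test_ndjson(self, tmp_path):
        path = tmp_path / "r.ndjson"
        path.write_text("\n".join(json.dumps(patient(f"p{i}")) for i in range(3)) + "\n")
        store = ResourceStore.load(path)
        assert store.count("Patient") == 3

    def test_bundle_equals_ndjson(self, tmp_path):
        resources = [patient("p1"), condition("c1", "p1", "A")]
        (tmp_path / "r.ndjson").write_text("\n".join(json.dumps(r) for r in resources))
        bundle = {"resourceType": "Bundle", "type": "collection",
                  "entry": [{"resource": r} for r in resources]}
        (tmp_path / "r.json").write_text(json.dumps(bundle))
        a = ResourceStore.load(tmp_path / "r.ndjson", format="ndjson")
        b = ResourceStore.load(tmp_path / "r.json", format="bundle")
        assert a.counts_by_type() == b.counts_by_type()
        assert a.to_ndjson() == b.to_ndjson()

    def test_empty_file_is_an_empty_store(self, tmp_path):
        path = tmp_path / "empty.ndjson"
        path.write_text("")
        assert ResourceStore.load(path).count() == 0

    def test_unknown_resource_type_is_skipped_with_count(self):
        store = ResourceStore.from_resources(
            [patient("p1"), {"resourceType": "Medication", "id": "m1"}], lenient=True)
        assert store.count() == 1
        assert store.skipped == 1

    def test_dangling_subject_is_strict_error(self):
        with pytest.raises(StoreError, match="missing Patient"):
            ResourceStore.from_resources([condition("c1", "ghost", "A")])
        lenient = ResourceStore.from_resources([condition("c1", "ghost", "A")], lenient=True)
        assert lenient.count("Condition") == 1

    def test_duplicate_id_rejected(self):
        with pytest.raises(StoreError, match="duplicate"):
            ResourceStore.from_resources([patient("p1"), patient("p1")])

    def test_ndjson_round_trip_preserves_counts_and_ids(self, tmp_path):
        store = random_store(random.Random(2), n_patients=8)
        path = tmp_path / "out.ndjson"
        store.save(path)
        reloaded = ResourceStore.load(path)
        assert reloaded.counts_by_type() == store.counts_by_type()
        assert {r["id"] for r in reloaded.iter_resources()} == {r["id"] for r in store.iter_resources()}


class TestSearch:
    def test_gender_token(self):
        store = ResourceStore.from_resources(
            [patient("p1"), patient("p2"), patient("p3", "male")])
        hits = store.search(atomic("Patient", ("gender", "female")))
        assert {r["id"] for r in hits} == {"p1", "p2"}

    def test_comma_is_or(self):
        store = ResourceStore.from_resources(
            [patient("p1"), condition("c1", "p1", "A"), condition("c2", "p1", "B"),
             condition("c3", "p1", "C")])
        hits = store.search(atomic("Condition", ("code", f"{ICD}%7CA,{ICD}%7CB")))
        assert {r["id"] for r in hits} == {"c1", "c2"}

    def test_bare_code_token_matches_any_system(self):
        store = ResourceStore.from_resources([patient("p1"), condition("c1", "p1", "A")])
        assert len(store.search(atomic("Condition", ("code", "A")))) == 1
        assert len(store.search(atomic("Condition", ("code", "urn:other%7CA")))) == 0

    def test_quantity_matches_brute_force(self):
        rng = random.Random(41)
        store = random_store(rng, n_patients=15)
        for prefix in ("gt", "ge", "lt", "le", "eq"):
            threshold = rng.randrange(1, 20)
            token = f"{prefix}{threshold}%7C{UCUM.replace(':', '%3A').replace('/', '%2F')}%7Cmg%2FdL"
            hits = store.search(atomic("Observation", ("code", "L1"), ("value-quantity", token)))
            ops = {"gt": lambda a, b: a > b, "ge": lambda a, b: a >= b,
                   "lt": lambda a, b: a < b, "le": lambda a, b: a <= b,
                   "eq": lambda a, b: a == b}
            expected = [
                r for r in store.resources("Observation")
                if any(c["code"] == "L1" for c in r["code"]["coding"])
                and ops[prefix](Decimal(str(r["valueQuantity"]["value"])), Decimal(threshold))
            ]
            assert [r["id"] for r in hits] == [r["id"] for r in expected]

    def test_quantity_requires_unit_match_when_given(self):
        store = ResourceStore.from_resources([patient("p1"), observation("o1", "p1", "L1", 5)])
        ok = atomic("Observation", ("value-quantity", f"eq5%7C{UCUM.replace(':', '%3A').replace('/', '%2F')}%7Cmg%2FdL"))
        wrong_unit = atomic("Observation", ("value-quantity", "eq5%7Curn:x%7Cmmol%2FL"))
        bare = atomic("Observation", ("value-quantity", "eq5"))
        assert len(store.search(ok)) == 1
        assert len(store.search(wrong_unit)) == 0
        assert len(store.search(bare)) == 1

    def test_date_range_inclusive_at_day_precision(self):
        store = ResourceStore.from_resources([
            patient("p1"),
            condition("c1", "p1", "A", "2020-01-01"),
            condition("c2", "p1", "A", "2020-06-15"),
            condition("c3", "p1", "A", "2020-12-31"),
        ])
        hits = store.search(atomic(
            "Condition", ("code", "A"),
            ("recorded-date", "ge2020-01-01"), ("recorded-date", "le2020-06-15")))
        assert {r["id"] for r in hits} == {"c1", "c2"}

    def test_unsupported_parameter_is_named(self):
        store = ResourceStore.from_resources([patient("p1")])
        with pytest.raises(UnsupportedSearch, match="_has"):
            store.search(atomic("Patient", ("_has", "x")))
        with pytest.raises(UnsupportedSearch, match="Medication"):
            store.search(atomic("Medication", ("code", "x")))

    def test_search_is_pure_and_repeatable(self):
        store = random_store(random.Random(8))
        before = store.to_ndjson()
        q = atomic("Condition", ("code", "A,B"))
        assert store.search(q) == store.search(q)
        assert store.to_ndjson() == before

    def test_search_equals_full_scan_on_random_stores(self):
        """Token+quantity+date conjunctions against a naive predicate scan."""
        rng = random.Random(55)
        for _ in range(25):
            store = random_store(rng, n_patients=10)
            code = rng.choice(("L1", "L2"))
            threshold = rng.randrange(1, 20)
            date = f"2020-0{rng.randrange(1, 9)}-01"
            q = atomic("Observation", ("code", code),
                       ("value-quantity", f"le{threshold}"), ("date", f"ge{date}"))
            naive = [
                r for r in store.resources("Observation")
                if any(c["code"] == code for c in r["code"]["coding"])
                and Decimal(str(r["valueQuantity"]["value"])) <= threshold
                and r["effectiveDateTime"][:10] >= date
            ]
            assert [r["id"] for r in store.search(q)] == [r["id"] for r in naive]


class TestPatientIds:
    def test_conditions_of_one_patient_dedupe(self):
        rs = [condition(f"c{i}", "p1", "A") for i in range(3)]
        assert patient_ids(rs) == {"p1"}

    def test_patient_resources_use_own_id(self):
        assert patient_ids([patient("p1"), patient("p2")]) == {"p1", "p2"}

    def test_missing_subject_is_an_error(self):
        with pytest.raises(StoreError, match="subject"):
            patient_ids([{"resourceType": "Condition", "id": "c1"}])

    def test_mixed_resources_match_manual_extraction(self):
        store = random_store(random.Random(77), n_patients=20)
        resources = store.resources("Condition") + store.resources("Observation")
        manual = {r["subject"]["reference"].split("/")[1] for r in resources}
        assert patient_ids(resources) == manual
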