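"""Shared fixtures: toy terminology, randomized stores/queries, and an
independent brute-force satisfaction oracle.

The oracle deliberately re-derives everything the library computes by a
different route: hierarchy expansion by its own recursive traversal,
criterion satisfaction by scanning raw resource dicts, and query
semantics via ``evaluate_reference`` over the resulting truth
assignments.  Executor results must coincide with it on every randomized
instance.
"""

from __future__ import annotations

import datetime
import random
from decimal import Decimal
from importlib import resources as importlib_resources
from typing import Optional

import pytest

from feasquery.query_model import (
    Criterion,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    StructuredQuery,
    TermCode,
    TimeRestriction,
)
from feasquery.store import ResourceStore
from feasquery.terminology import MappingEntry, MappingTable, TermTree, TermTreeNode

ICD = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
OPS = "http://fhir.de/CodeSystem/bfarm/ops"
LOINC = "http://loinc.org"
GENDER = "http://hl7.org/fhir/administrative-gender"
UCUM = "http://unitsofmeasure.org"


def _fixture_text(name: str) -> str:
    return importlib_resources.files("feasquery.data").joinpath(name).read_text(encoding="utf-8")


@pytest.fixture(scope="session")
def toy_tree() -> TermTree:
    return TermTree.from_json(_fixture_text("toy-term-tree.json"))


@pytest.fixture(scope="session")
def toy_mapping() -> MappingTable:
    return MappingTable.from_json(_fixture_text("toy-mapping.json"))


# --------------------------------------------------------------------------
# randomized instance harness
# --------------------------------------------------------------------------

def _node(system: str, code: str, *children: TermTreeNode) -> TermTreeNode:
    return TermTreeNode(term_code=TermCode(system=system, code=code), children=list(children))


def harness_terminology() -> tuple[TermTree, MappingTable]:
    """A small universe with real hierarchy: conditions A (A.1 (A.1.1), A.2), B;
    procedure P1; observations L1, L2; the four administrative genders."""
    tree = TermTree([
        _node(ICD, "A", _node(ICD, "A.1", _node(ICD, "A.1.1")), _node(ICD, "A.2")),
        _node(ICD, "B"),
        _node(OPS, "P1"),
        _node(LOINC, "L1"),
        _node(LOINC, "L2"),
        *[_node(GENDER, g) for g in ("female", "male", "other", "unknown")],
    ])
    entries = []
    for code in ("A", "A.1", "A.1.1", "A.2", "B"):
        entries.append(MappingEntry(
            key=TermCode(system=ICD, code=code), fhir_resource_type="Condition",
            term_code_search_parameter="code", time_restriction_parameter="recorded-date"))
    entries.append(MappingEntry(
        key=TermCode(system=OPS, code="P1"), fhir_resource_type="Procedure",
        term_code_search_parameter="code", time_restriction_parameter="date"))
    for code in ("L1", "L2"):
        entries.append(MappingEntry(
            key=TermCode(system=LOINC, code=code), fhir_resource_type="Observation",
            term_code_search_parameter="code", value_search_parameter="value-quantity",
            time_restriction_parameter="date"))
    for g in ("female", "male", "other", "unknown"):
        entries.append(MappingEntry(
            key=TermCode(system=GENDER, code=g), fhir_resource_type="Patient",
            term_code_search_parameter="gender", token_form="code"))
    return tree, MappingTable(entries)


@pytest.fixture(scope="session")
def harness():
    return harness_terminology()


_CONDITION_CODES = ("A", "A.1", "A.1.1", "A.2", "B")
_DATE_POOL = [datetime.date(2020, 1, 1) + datetime.timedelta(days=30 * k) for k in range(24)]


def random_store(rng: random.Random, n_patients: int = 12) -> ResourceStore:
    """A random store over the harness universe."""
    resources = []
    serial = 0
    for i in range(n_patients):
        pid = f"p{i}"
        resources.append({
            "resourceType": "Patient", "id": pid,
            "gender": rng.choice(("female", "male", "other", "unknown")),
            "birthDate": "1970-01-01",
        })
        for _ in range(rng.randrange(0, 3)):
            resources.append({
                "resourceType": "Condition", "id": f"c{serial}",
                "code": {"coding": [{"system": ICD, "code": rng.choice(_CONDITION_CODES)}]},
                "subject": {"reference": f"Patient/{pid}"},
                "recordedDate": rng.choice(_DATE_POOL).isoformat(),
            })
            serial += 1
        for _ in range(rng.randrange(0, 2)):
            resources.append({
                "resourceType": "Procedure", "id": f"pr{serial}",
                "code": {"coding": [{"system": OPS, "code": "P1"}]},
                "subject": {"reference": f"Patient/{pid}"},
                "performedDateTime": rng.choice(_DATE_POOL).isoformat(),
            })
            serial += 1
        for _ in range(rng.randrange(0, 3)):
            resources.append({
                "resourceType": "Observation", "id": f"o{serial}",
                "code": {"coding": [{"system": LOINC, "code": rng.choice(("L1", "L2"))}]},
                "subject": {"reference": f"Patient/{pid}"},
                "valueQuantity": {"value": rng.randrange(1, 20), "unit": "mg/dL", "system": UCUM},
                "effectiveDateTime": rng.choice(_DATE_POOL).isoformat(),
            })
            serial += 1
    return ResourceStore.from_resources(resources)


def random_criterion(rng: random.Random) -> Criterion:
    kind = rng.randrange(4)
    time_restriction: Optional[TimeRestriction] = None
    if rng.random() < 0.3:
        a, b = sorted(rng.sample(_DATE_POOL, 2))
        time_restriction = TimeRestriction(after_date=a, before_date=b)
    if kind == 0:
        return Criterion(term_codes=[TermCode(
            system=GENDER, code=rng.choice(("female", "male", "other", "unknown")))])
    if kind == 1:
        return Criterion(
            term_codes=[TermCode(system=ICD, code=rng.choice(_CONDITION_CODES))],
            time_restriction=time_restriction,
        )
    if kind == 2:
        return Criterion(term_codes=[TermCode(system=OPS, code="P1")],
                         time_restriction=time_restriction)
    value_filter = None
    roll = rng.random()
    if roll < 0.4:
        value_filter = QuantityComparatorFilter(
            kind="quantity-comparator",
            comparator=rng.choice(("gt", "ge", "lt", "le", "eq")),
            value=Decimal(rng.randrange(1, 20)),
            unit="mg/dL",
        )
    elif roll < 0.6:
        lo, hi = sorted(rng.sample(range(1, 20), 2))
        value_filter = QuantityRangeFilter(
            kind="quantity-range", min_value=Decimal(lo), max_value=Decimal(hi), unit="mg/dL")
    return Criterion(
        term_codes=[TermCode(system=LOINC, code=rng.choice(("L1", "L2")))],
        value_filter=value_filter,
        time_restriction=time_restriction,
    )


def random_query(rng: random.Random, max_criteria: int = 3) -> StructuredQuery:
    n_inc = rng.randrange(1, max_criteria + 1)
    inclusion = [
        [random_criterion(rng) for _ in range(rng.randrange(1, 3))] for _ in range(n_inc)
    ]
    exclusion = []
    if rng.random() < 0.5:
        exclusion = [
            [random_criterion(rng) for _ in range(rng.randrange(1, 3))]
            for _ in range(rng.randrange(1, 3))
        ]
    return StructuredQuery(inclusion_criteria=inclusion, exclusion_criteria=exclusion)


# --------------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------------

def _descendants(node: TermTreeNode) -> set[tuple[str, str]]:
    out = {(node.term_code.system, node.term_code.code)}
    for child in node.children:
        out |= _descendants(child)
    return out


def _expansion_set(tree: TermTree, code: TermCode) -> set[tuple[str, str]]:
    node = tree.find(code)
    if node is None:
        return {(code.system, code.code)}
    return _descendants(node)


def _within(date_str: str, tr: Optional[TimeRestriction]) -> bool:
    if tr is None:
        return True
    d = datetime.date.fromisoformat(date_str[:10])
    if tr.after_date is not None and d < tr.after_date:
        return False
    if tr.before_date is not None and d > tr.before_date:
        return False
    return True


def _value_ok(quantity: dict, vf) -> bool:
    if vf is None:
        return True
    v = Decimal(str(quantity["value"]))
    if isinstance(vf, QuantityComparatorFilter):
        if quantity.get("unit") != vf.unit:
            return False
        return {
            "gt": v > vf.value, "ge": v >= vf.value, "lt": v < vf.value,
            "le": v <= vf.value, "eq": v == vf.value,
        }[vf.comparator]
    if isinstance(vf, QuantityRangeFilter):
        return quantity.get("unit") == vf.unit and vf.min_value <= v <= vf.max_value
    raise NotImplementedError(type(vf))


_DATE_FIELDS = {"Condition": "recordedDate", "Procedure": "performedDateTime",
                "Observation": "effectiveDateTime"}


def brute_force_satisfies(store: ResourceStore, tree: TermTree, patient: dict,
                          criterion: Criterion) -> bool:
    """Does this patient satisfy the criterion?  Full scan, no indexes."""
    wanted: set[tuple[str, str]] = set()
    for t in criterion.term_codes:
        wanted |= _expansion_set(tree, t)
    if any(system == GENDER for system, _ in wanted):
        return patient.get("gender") in {code for _, code in wanted}
    pid = patient["id"]
    for rtype, date_field in _DATE_FIELDS.items():
        for r in store.resources(rtype):
            if r["subject"]["reference"] != f"Patient/{pid}":
                continue
            codings = {(c.get("system"), c.get("code")) for c in r["code"]["coding"]}
            if not (codings & wanted):
                continue
            if not _within(r[date_field], criterion.time_restriction):
                continue
            if criterion.value_filter is not None:
                if rtype != "Observation" or not _value_ok(r["valueQuantity"], criterion.value_filter):
                    continue
            return True
    return False


def truth_assignments(store: ResourceStore, tree: TermTree,
                      q: StructuredQuery) -> dict[str, set[Criterion]]:
    criteria = set(q.criteria())
    return {
        patient["id"]: {c for c in criteria if brute_force_satisfies(store, tree, patient, c)}
        for patient in store.resources("Patient")
    }
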