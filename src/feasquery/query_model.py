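"""The Structured Query: the formal representation of a cohort feasibility query.

A feasibility query asks how many patients satisfy a combination of
eligibility criteria.  Inclusion criteria are combined in conjunctive
normal form (an AND of OR-groups) and exclusion criteria in disjunctive
normal form (an OR of AND-groups).  A patient is in the cohort iff every
inclusion group contains at least one satisfied criterion and no
exclusion group is satisfied in full:

    match(p) = [∀ g ∈ inclusion: ∃ c ∈ g: sat(p, c)]
               ∧ ¬[∃ g ∈ exclusion: ∀ c ∈ g: sat(p, c)]

Each criterion names a medical concept by one or more term codes — a
(code system, code) pair such as an ICD-10 diagnosis, an OPS procedure,
or a LOINC laboratory code — optionally restricted by a value filter
(coded value or measured quantity) and a time window.

This module defines the JSON dialect (parse / serialize, strict about
unknown fields), its validation invariants, and a brute-force reference
evaluator used as the correctness oracle for the executable paths.
"""

from __future__ import annotations

import datetime
import json
from decimal import Decimal
from typing import Annotated, Collection, Literal, Mapping, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator
from pydantic.alias_generators import to_camel

__all__ = [
    "TermCode",
    "ConceptFilter",
    "QuantityComparatorFilter",
    "QuantityRangeFilter",
    "ValueFilter",
    "TimeRestriction",
    "Criterion",
    "StructuredQuery",
    "QueryValidationError",
    "parse_structured_query",
    "serialize_structured_query",
    "evaluate_reference",
]

#: Comparators allowed in quantity filters.  ``ne`` is deliberately absent:
#: negated token searches are not reliably expressible in FHIR Search, so the
#: dialect never produces a criterion that would need one.
Comparator = Literal["gt", "ge", "lt", "le", "eq"]


class QueryValidationError(ValueError):
    """A Structured Query document violates the dialect's invariants."""


class _Model(BaseModel):
    """Base config: frozen values, camelCase wire names, unknown fields rejected."""

    model_config = ConfigDict(
        frozen=True,
        extra="forbid",
        alias_generator=to_camel,
        populate_by_name=True,
    )


class TermCode(_Model):
    """A concept identifier: a code within a code system.

    Equality and hashing use ``(system, code)`` only; ``display`` is
    human-readable garnish and never participates in comparisons.
    """

    system: str = Field(min_length=1)
    code: str = Field(min_length=1)
    display: str = ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermCode):
            return NotImplemented
        return (self.system, self.code) == (other.system, other.code)

    def __hash__(self) -> int:
        return hash((self.system, self.code))

    def __str__(self) -> str:
        return f"{self.system}|{self.code}"


class ConceptFilter(_Model):
    """Restrict a criterion to observations carrying one of several coded values."""

    kind: Literal["concept"]
    selected_concepts: list[TermCode] = Field(min_length=1)

    def _key(self) -> tuple:
        return ("concept", tuple((c.system, c.code) for c in self.selected_concepts))


class QuantityComparatorFilter(_Model):
    """Restrict to measured values satisfying ``value <cmp> threshold`` in a UCUM unit."""

    kind: Literal["quantity-comparator"]
    comparator: Comparator
    value: Decimal
    unit: str = Field(min_length=1)

    def _key(self) -> tuple:
        return ("quantity-comparator", self.comparator, str(self.value), self.unit)


class QuantityRangeFilter(_Model):
    """Restrict to measured values within an inclusive range in a UCUM unit."""

    kind: Literal["quantity-range"]
    min_value: Decimal
    max_value: Decimal
    unit: str = Field(min_length=1)

    @model_validator(mode="after")
    def _ordered(self) -> "QuantityRangeFilter":
        if self.min_value > self.max_value:
            raise ValueError(f"minValue {self.min_value} exceeds maxValue {self.max_value}")
        return self

    def _key(self) -> tuple:
        return ("quantity-range", str(self.min_value), str(self.max_value), self.unit)


ValueFilter = Annotated[
    Union[ConceptFilter, QuantityComparatorFilter, QuantityRangeFilter],
    Field(discriminator="kind"),
]


class TimeRestriction(_Model):
    """A calendar-date window; both bounds inclusive, at least one present."""

    after_date: Optional[datetime.date] = None
    before_date: Optional[datetime.date] = None

    @model_validator(mode="after")
    def _bounds(self) -> "TimeRestriction":
        if self.after_date is None and self.before_date is None:
            raise ValueError("timeRestriction needs afterDate and/or beforeDate")
        if self.after_date is not None and self.before_date is not None:
            if self.after_date > self.before_date:
                raise ValueError(f"afterDate {self.after_date} is after beforeDate {self.before_date}")
        return self

    def _key(self) -> tuple:
        return (str(self.after_date), str(self.before_date))


class Criterion(_Model):
    """One selectable concept, optionally value- and time-restricted.

    ``termCodes`` lists alternative codes naming the same concept (e.g. the
    same laboratory analyte in two code systems); a resource matching any of
    them, or any hierarchical descendant, satisfies the criterion.
    """

    term_codes: list[TermCode] = Field(min_length=1)
    value_filter: Optional[ValueFilter] = None
    time_restriction: Optional[TimeRestriction] = None

    def __hash__(self) -> int:
        vf = self.value_filter._key() if self.value_filter is not None else None
        tr = self.time_restriction._key() if self.time_restriction is not None else None
        return hash((tuple((t.system, t.code) for t in self.term_codes), vf, tr))


class StructuredQuery(_Model):
    """A full feasibility query: CNF inclusion groups, DNF exclusion groups."""

    version: str = "feasquery-1"
    inclusion_criteria: list[list[Criterion]] = Field(min_length=1)
    exclusion_criteria: list[list[Criterion]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _no_empty_groups(self) -> "StructuredQuery":
        for label, groups in (("inclusionCriteria", self.inclusion_criteria),
                              ("exclusionCriteria", self.exclusion_criteria)):
            for i, group in enumerate(groups):
                if not group:
                    raise ValueError(f"{label}[{i}] is an empty criterion group")
        return self

    def criteria(self) -> list[Criterion]:
        """All criteria in document order (inclusion groups, then exclusion)."""
        out: list[Criterion] = []
        for group in self.inclusion_criteria:
            out.extend(group)
        for group in self.exclusion_criteria:
            out.extend(group)
        return out

    def __hash__(self) -> int:
        return hash((
            self.version,
            tuple(tuple(hash(c) for c in g) for g in self.inclusion_criteria),
            tuple(tuple(hash(c) for c in g) for g in self.exclusion_criteria),
        ))


def parse_structured_query(document: str) -> StructuredQuery:
    """Parse and validate a Structured Query JSON document.

    Unknown fields are rejected with a diagnostic naming the offending
    field path, so dialect drift surfaces immediately instead of silently
    altering cohort semantics.

    Raises
    ------
    QueryValidationError
        On malformed JSON or any invariant violation.
    """
    try:
        raw = json.loads(document)
    except json.JSONDecodeError as exc:
        raise QueryValidationError(f"malformed JSON: {exc}") from exc
    try:
        return StructuredQuery.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(part) for part in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise QueryValidationError(f"invalid Structured Query: {paths}") from exc


def serialize_structured_query(q: StructuredQuery) -> str:
    """Serialize to canonical JSON: fixed key order, no absent fields.

    ``parse_structured_query(serialize_structured_query(q)) == q`` for every
    valid query, and the output is byte-identical across runs.
    """
    payload = q.model_dump(mode="json", by_alias=True, exclude_none=True)
    return json.dumps(payload, ensure_ascii=False, separators=(", ", ": "), indent=1)


def evaluate_reference(
    q: StructuredQuery,
    patients: Mapping[str, Collection[Criterion]],
) -> set[str]:
    """Brute-force oracle for the CNF/DNF semantic contract.

    ``patients`` maps each patient identifier to the collection of criteria
    that patient satisfies (a precomputed truth assignment).  Returns the
    identifiers matching the query by direct boolean evaluation — no
    translation, no index, no set algebra — so the executable query paths
    can be checked against it.
    """
    matched: set[str] = set()
    for pid, facts in patients.items():
        included = all(any(c in facts for c in group) for group in q.inclusion_criteria)
        excluded = any(all(c in facts for c in group) for group in q.exclusion_criteria)
        if included and not excluded:
            matched.add(pid)
    return matched
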