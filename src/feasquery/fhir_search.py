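"""Translate Structured Queries into FHIR Search execution plans.

FHIR Search cannot express a multi-criterion feasibility query in one
request, so each criterion becomes one *bundle* of atomic FHIR Search
queries (more than one only when its expanded code list is chunked to
keep URLs short).  The bundles are arranged in an execution plan whose
shape mirrors the Structured Query — CNF inclusion groups, DNF exclusion
groups — and is later combined by set algebra over patient identifiers.

Rendering conventions:

* token values are ``system|code`` by default (bare ``code`` only where a
  mapping opts in, e.g. ``Patient?gender=female``);
* quantities use the ``<prefix><value>|<system>|<unit>`` token form with
  the UCUM system URI;
* dates use ``ge``/``le`` prefixes on the mapping's date parameter;
* parameter order is deterministic: term-code, then value, then time;
* values are percent-encoded per token, commas separate OR-ed tokens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from urllib.parse import quote, unquote

from feasquery.query_model import (
    ConceptFilter,
    Criterion,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    StructuredQuery,
    TermCode,
)
from feasquery.terminology import MappingEntry, MappingTable, TermTree, expand_code, lookup_mapping

__all__ = [
    "AtomicQuery",
    "ExecutionPlan",
    "TranslationError",
    "UCUM_SYSTEM",
    "criterion_to_queries",
    "build_plan",
    "parse_query_url",
    "DEFAULT_CHUNK_SIZE",
]

UCUM_SYSTEM = "http://unitsofmeasure.org"

#: Codes per atomic query.  FHIR Search carries code lists in the URL, and
#: very long URLs are rejected by many HTTP stacks; 200 ``system|code``
#: tokens stay comfortably under common 8 kB limits.
DEFAULT_CHUNK_SIZE = 200


class TranslationError(ValueError):
    """A criterion cannot be translated (never silently dropped)."""


@dataclass(frozen=True)
class AtomicQuery:
    """One FHIR Search request: a resource type plus ordered parameters."""

    resource_type: str
    parameters: tuple[tuple[str, str], ...]
    source_criterion: Criterion

    def render(self) -> str:
        """Relative-URL form ``Type?name=value&…`` with per-token percent-encoding."""
        params = "&".join(f"{name}={value}" for name, value in self.parameters)
        return f"{self.resource_type}?{params}"


@dataclass(frozen=True)
class ExecutionPlan:
    """All atomic queries of one Structured Query, grouped as the query is.

    ``inclusion[g][c]`` is the bundle (list of chunked atomic queries) of
    criterion ``c`` in inclusion group ``g``; likewise ``exclusion``.  The
    group and criterion counts equal those of the source query.
    """

    inclusion: tuple[tuple[tuple[AtomicQuery, ...], ...], ...]
    exclusion: tuple[tuple[tuple[AtomicQuery, ...], ...], ...]
    query: StructuredQuery = field(repr=False)

    def atomic_queries(self) -> list[AtomicQuery]:
        out = []
        for section in (self.inclusion, self.exclusion):
            for group in section:
                for bundle in group:
                    out.extend(bundle)
        return out


def _encode_token(token: str) -> str:
    return quote(token, safe="")


def _code_token(entry: MappingEntry, code: TermCode) -> str:
    if entry.token_form == "code":
        return _encode_token(code.code)
    return _encode_token(f"{code.system}|{code.code}")


def _value_parameters(c: Criterion, entry: MappingEntry) -> list[tuple[str, str]]:
    vf = c.value_filter
    if vf is None:
        return []
    param = entry.value_search_parameter
    if param is None:
        raise TranslationError(
            f"criterion {c.term_codes[0]} has a value filter but mapping provides no valueSearchParameter"
        )
    if isinstance(vf, ConceptFilter):
        tokens = ",".join(_encode_token(f"{t.system}|{t.code}") for t in vf.selected_concepts)
        return [(param, tokens)]
    if isinstance(vf, QuantityComparatorFilter):
        token = f"{vf.comparator}{vf.value}|{UCUM_SYSTEM}|{vf.unit}"
        return [(param, _encode_token(token))]
    if isinstance(vf, QuantityRangeFilter):
        return [
            (param, _encode_token(f"ge{vf.min_value}|{UCUM_SYSTEM}|{vf.unit}")),
            (param, _encode_token(f"le{vf.max_value}|{UCUM_SYSTEM}|{vf.unit}")),
        ]
    raise TranslationError(f"unsupported value filter kind {vf.kind!r}")  # pragma: no cover


def _time_parameters(c: Criterion, entry: MappingEntry) -> list[tuple[str, str]]:
    tr = c.time_restriction
    if tr is None:
        return []
    param = entry.time_restriction_parameter
    if param is None:
        raise TranslationError(
            f"criterion {c.term_codes[0]} has a time restriction but mapping provides no "
            "timeRestrictionParameter"
        )
    out = []
    if tr.after_date is not None:
        out.append((param, f"ge{tr.after_date.isoformat()}"))
    if tr.before_date is not None:
        out.append((param, f"le{tr.before_date.isoformat()}"))
    return out


def criterion_to_queries(
    c: Criterion,
    tree: TermTree,
    mapping: MappingTable,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> list[AtomicQuery]:
    """Translate one criterion into its bundle of atomic FHIR Search queries.

    All term codes are expanded to their hierarchical descendants,
    deduplicated (first occurrence wins), and split into
    ``ceil(n / chunk_size)`` queries whose results are unioned downstream.
    Every query in the bundle carries the criterion's value and time
    parameters unchanged.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be positive, got {chunk_size}")
    entries = [lookup_mapping(mapping, t) for t in c.term_codes]
    entry = entries[0]
    for other, t in zip(entries[1:], c.term_codes[1:]):
        if other.fhir_resource_type != entry.fhir_resource_type:
            raise TranslationError(
                f"criterion mixes resource types: {c.term_codes[0]} -> {entry.fhir_resource_type}, "
                f"{t} -> {other.fhir_resource_type}"
            )

    codes: list[TermCode] = []
    seen: set[TermCode] = set()
    for t in c.term_codes:
        for code in expand_code(tree, t):
            if code not in seen:
                seen.add(code)
                codes.append(code)

    tail = _value_parameters(c, entry) + _time_parameters(c, entry)
    queries: list[AtomicQuery] = []
    for i in range(0, len(codes), chunk_size):
        chunk = codes[i : i + chunk_size]
        params: list[tuple[str, str]] = []
        if entry.term_code_search_parameter is not None:
            tokens = ",".join(_code_token(entry, code) for code in chunk)
            params.append((entry.term_code_search_parameter, tokens))
        params.extend(tail)
        queries.append(AtomicQuery(entry.fhir_resource_type, tuple(params), c))
    if not queries:  # pragma: no cover - codes is never empty (termCodes non-empty)
        raise TranslationError("criterion produced no queries")
    assert len(queries) == math.ceil(len(codes) / chunk_size)
    return queries


def build_plan(
    q: StructuredQuery,
    tree: TermTree,
    mapping: MappingTable,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> ExecutionPlan:
    """Translate a whole Structured Query; the first untranslatable criterion aborts."""

    def section(groups: list[list[Criterion]]):
        return tuple(
            tuple(tuple(criterion_to_queries(c, tree, mapping, chunk_size)) for c in group)
            for group in groups
        )

    return ExecutionPlan(
        inclusion=section(q.inclusion_criteria),
        exclusion=section(q.exclusion_criteria),
        query=q,
    )


def parse_query_url(url: str) -> tuple[str, list[tuple[str, list[str]]]]:
    """Parse a rendered atomic-query URL back into (resourceType, parameters).

    Each parameter value is split on the comma OR-separator and
    percent-decoded per token.  Inverse of :meth:`AtomicQuery.render`; used
    to verify that rendering is lossless.
    """
    resource_type, _, rest = url.partition("?")
    params: list[tuple[str, list[str]]] = []
    if rest:
        for pair in rest.split("&"):
            name, _, value = pair.partition("=")
            params.append((name, [unquote(tok) for tok in value.split(",")]))
    return resource_type, params
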