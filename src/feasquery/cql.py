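"""Translate Structured Queries into CQL library text.

CQL (Clinical Quality Language) can express a whole feasibility query in
a single library, which a CQL-capable FHIR server executes directly.
This module generates that text: a ``library`` header, one ``codesystem``
declaration per distinct code system (aliased ``cs0``, ``cs1``, … in
first-use order), ``context Patient``, one ``define`` per criterion
(an exists-retrieve over the criterion's expanded code list, with value
and date clauses where filtered), and ``define InInitialPopulation``
combining the criterion defines with ``and`` / ``or`` / ``not`` following
the CNF inclusion and negated DNF exclusion contract.

Generation is deterministic: identical queries yield byte-identical text.
CQL *execution* is out of scope — semantic correctness is carried by the
FHIR Search path plus a boolean-skeleton equivalence check in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from feasquery.query_model import (
    ConceptFilter,
    Criterion,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    StructuredQuery,
    TermCode,
)
from feasquery.terminology import MappingTable, TermTree, expand_code, lookup_mapping

__all__ = ["CqlLibrary", "build_cql_library", "translate_to_cql"]

_CQL_COMPARATORS = {"gt": ">", "ge": ">=", "lt": "<", "le": "<=", "eq": "="}

#: CQL path expression for each resource type's primary clinical date.
_DATE_PATHS = {
    "Condition": "recordedDate",
    "Procedure": "performed",
    "Observation": "effective",
}


@dataclass(frozen=True)
class CqlLibrary:
    """A generated CQL library, decomposed for inspection."""

    name: str
    fhir_version: str
    codesystem_decls: tuple[tuple[str, str], ...]  # (alias, system URI)
    criterion_defines: tuple[tuple[str, str], ...]  # (define name, body text)
    population_expression: str

    @property
    def text(self) -> str:
        lines = [
            f"library {self.name} version '1.0.0'",
            f"using FHIR version '{self.fhir_version}'",
            "",
        ]
        for alias, system in self.codesystem_decls:
            lines.append(f"codesystem {alias}: '{system}'")
        if self.codesystem_decls:
            lines.append("")
        lines.append("context Patient")
        lines.append("")
        for name, body in self.criterion_defines:
            lines.append(f"define {name}:")
            lines.append(f"  {body}")
            lines.append("")
        lines.append("define InInitialPopulation:")
        lines.append(f"  {self.population_expression}")
        return "\n".join(lines) + "\n"


class _SystemAliases:
    def __init__(self) -> None:
        self._aliases: dict[str, str] = {}

    def alias(self, system: str) -> str:
        if system not in self._aliases:
            self._aliases[system] = f"cs{len(self._aliases)}"
        return self._aliases[system]

    def declarations(self) -> tuple[tuple[str, str], ...]:
        return tuple((alias, system) for system, alias in self._aliases.items())


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace("'", "\\'")


def _retrieve(resource_type: str, code: TermCode, aliases: _SystemAliases) -> str:
    return f"[{resource_type}: Code '{_escape(code.code)}' from {aliases.alias(code.system)}]"


def _criterion_define(
    c: Criterion, tree: TermTree, mapping: MappingTable, aliases: _SystemAliases
) -> str:
    entry = lookup_mapping(mapping, c.term_codes[0])
    for t in c.term_codes[1:]:
        lookup_mapping(mapping, t)  # fail loudly on any unmapped alternative

    codes: list[TermCode] = []
    seen: set[TermCode] = set()
    for t in c.term_codes:
        for code in expand_code(tree, t):
            if code not in seen:
                seen.add(code)
                codes.append(code)
    # declare systems in expansion order even for patient-level criteria
    for code in codes:
        aliases.alias(code.system)

    if entry.fhir_resource_type == "Patient":
        field = entry.term_code_search_parameter or "gender"
        clauses = [f"Patient.{field} = '{_escape(code.code)}'" for code in codes]
        body = " or ".join(clauses)
        return f"({body})" if len(clauses) > 1 else body

    retrieves = [_retrieve(entry.fhir_resource_type, code, aliases) for code in codes]
    source = " union ".join(f"({r})" for r in retrieves) if len(retrieves) > 1 else retrieves[0]

    clauses = _filter_clauses(c, entry.fhir_resource_type, aliases)
    if not clauses:
        return f"exists ({source})"
    where = " and ".join(clauses)
    return f"exists (({source}) R where {where})"


def _filter_clauses(c: Criterion, resource_type: str, aliases: _SystemAliases) -> list[str]:
    clauses: list[str] = []
    vf = c.value_filter
    if isinstance(vf, QuantityComparatorFilter):
        op = _CQL_COMPARATORS[vf.comparator]
        clauses.append(f"(R.value as Quantity) {op} {vf.value} '{_escape(vf.unit)}'")
    elif isinstance(vf, QuantityRangeFilter):
        clauses.append(f"(R.value as Quantity) >= {vf.min_value} '{_escape(vf.unit)}'")
        clauses.append(f"(R.value as Quantity) <= {vf.max_value} '{_escape(vf.unit)}'")
    elif isinstance(vf, ConceptFilter):
        alts = [
            f"(R.value as CodeableConcept) ~ Code '{_escape(t.code)}' from {aliases.alias(t.system)}"
            for t in vf.selected_concepts
        ]
        clauses.append("(" + " or ".join(alts) + ")" if len(alts) > 1 else alts[0])
    tr = c.time_restriction
    if tr is not None:
        path = _DATE_PATHS[resource_type]
        if tr.after_date is not None:
            clauses.append(f"R.{path} >= @{tr.after_date.isoformat()}")
        if tr.before_date is not None:
            clauses.append(f"R.{path} <= @{tr.before_date.isoformat()}")
    return clauses


def _population_expression(q: StructuredQuery, names: list[str]) -> str:
    it = iter(names)
    inclusion_groups = []
    for group in q.inclusion_criteria:
        members = [next(it) for _ in group]
        inclusion_groups.append("(" + " or ".join(members) + ")")
    inclusion = " and ".join(inclusion_groups)
    if len(inclusion_groups) > 1:
        inclusion = f"({inclusion})"

    if not q.exclusion_criteria:
        return inclusion

    exclusion_groups = []
    for group in q.exclusion_criteria:
        members = [next(it) for _ in group]
        exclusion_groups.append("(" + " and ".join(members) + ")")
    exclusion = " or ".join(exclusion_groups)
    if len(exclusion_groups) > 1:
        exclusion = f"({exclusion})"
    return f"{inclusion} and not {exclusion}"


def build_cql_library(
    q: StructuredQuery,
    tree: TermTree,
    mapping: MappingTable,
    name: str = "FeasibilityQuery",
    fhir_version: str = "4.0.1",
) -> CqlLibrary:
    """Build the decomposed CQL library for ``q``."""
    aliases = _SystemAliases()
    defines: list[tuple[str, str]] = []
    names: list[str] = []
    for i, c in enumerate(q.criteria()):
        define_name = f"Criterion_{i}"
        body = _criterion_define(c, tree, mapping, aliases)
        display = c.term_codes[0].display
        if display:
            body = f"// {display}\n  {body}"
        defines.append((define_name, body))
        names.append(define_name)
    return CqlLibrary(
        name=name,
        fhir_version=fhir_version,
        codesystem_decls=aliases.declarations(),
        criterion_defines=tuple(defines),
        population_expression=_population_expression(q, names),
    )


def translate_to_cql(
    q: StructuredQuery,
    tree: TermTree,
    mapping: MappingTable,
    name: str = "FeasibilityQuery",
) -> str:
    """Render ``q`` as a single CQL library text defining ``InInitialPopulation``."""
    return build_cql_library(q, tree, mapping, name=name).text
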