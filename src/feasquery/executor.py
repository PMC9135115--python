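"""Execute FHIR Search execution plans by set algebra over patient identifiers.

Each criterion bundle yields the union of patient-ID sets over its chunked
atomic queries; within an inclusion group criteria are OR-ed (union),
inclusion groups are AND-ed (intersection); within an exclusion group
criteria are AND-ed (intersection), exclusion groups OR-ed (union); the
cohort is the inclusion set minus the exclusion set.

Every atomic query is executed — deliberately without short-circuiting or
reordering, the worst-case discipline under which the benchmark design's
resources-processed accounting is exact and deterministic: the
``resources_processed`` tally is the total number of resources returned
across all atomic queries.
"""

from __future__ import annotations

from dataclasses import dataclass

from feasquery.fhir_search import DEFAULT_CHUNK_SIZE, AtomicQuery, ExecutionPlan, build_plan
from feasquery.query_model import StructuredQuery
from feasquery.store import ResourceStore, patient_ids
from feasquery.terminology import MappingTable, TermTree

__all__ = ["ExecutionResult", "execute_plan", "count_query"]


@dataclass(frozen=True)
class ExecutionResult:
    """Outcome of one plan execution at one site, before obfuscation."""

    patient_ids: frozenset[str]
    resources_processed: int

    @property
    def patient_count(self) -> int:
        return len(self.patient_ids)

    def to_json_dict(self) -> dict:
        return {"patientCount": self.patient_count, "resourcesProcessed": self.resources_processed}


class _Tally:
    def __init__(self, store: ResourceStore):
        self.store = store
        self.resources = 0

    def bundle_ids(self, bundle: tuple[AtomicQuery, ...]) -> set[str]:
        ids: set[str] = set()
        for q in bundle:
            hits = self.store.search(q)
            self.resources += len(hits)
            ids |= patient_ids(hits)
        return ids


def execute_plan(plan: ExecutionPlan, store: ResourceStore) -> ExecutionResult:
    """Run every atomic query of ``plan`` against ``store`` and combine the results."""
    if not plan.inclusion:
        raise ValueError("execution plan has no inclusion groups")
    tally = _Tally(store)

    included: set[str] | None = None
    for group in plan.inclusion:
        group_ids: set[str] = set()
        for bundle in group:
            group_ids |= tally.bundle_ids(bundle)
        included = group_ids if included is None else included & group_ids

    excluded: set[str] = set()
    for group in plan.exclusion:
        group_ids = None
        for bundle in group:
            ids = tally.bundle_ids(bundle)
            group_ids = ids if group_ids is None else group_ids & ids
        excluded |= group_ids or set()

    assert included is not None
    return ExecutionResult(
        patient_ids=frozenset(included - excluded),
        resources_processed=tally.resources,
    )


def count_query(
    q: StructuredQuery,
    store: ResourceStore,
    tree: TermTree,
    mapping: MappingTable,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> ExecutionResult:
    """Convenience composition: translate ``q`` into a plan and execute it."""
    return execute_plan(build_plan(q, tree, mapping, chunk_size), store)
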