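"""Pull-based multi-site simulation: one central broker, N hospital sites.

The broker never calls into a site — hospital firewalls forbid inbound
connections — so each site polls the broker, pulls the pending query
envelope, executes it locally against its own resource store, and posts
back a single obfuscated count.  The envelope carries *both* query
representations (Structured Query JSON and CQL text) so every site can
choose its execution path without central reconfiguration; in this
simulation only the FHIR-Search decomposition path is executable, and
configuring the ``cql`` path fails fast at site construction.

The simulation is in-process: the broker/site boundary is an interface
contract, not a transport, so a real HTTP middleware could be substituted
without touching the protocol semantics verified here.  Exact counts
never cross the site boundary — only :class:`~feasquery.privacy.ObfuscatedCount`
values appear in site results and reports.
"""

from __future__ import annotations

import datetime
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from feasquery.executor import count_query
from feasquery.fhir_search import DEFAULT_CHUNK_SIZE
from feasquery.privacy import ObfuscatedCount, obfuscate
from feasquery.query_model import StructuredQuery, parse_structured_query, serialize_structured_query
from feasquery.cql import translate_to_cql
from feasquery.store import ResourceStore
from feasquery.terminology import MappingTable, TermTree

__all__ = [
    "QueryEnvelope",
    "Site",
    "SiteResult",
    "Broker",
    "ConfigurationError",
    "make_envelope",
    "broadcast",
    "summarize",
    "load_network",
]

EXECUTION_PATHS = ("fhir-search",)  # "cql" is reserved: carried in the envelope, not executable


class ConfigurationError(ValueError):
    """The network or a site is misconfigured."""


@dataclass(frozen=True)
class QueryEnvelope:
    """Everything a site needs to answer one feasibility query."""

    query_id: str
    structured_query: str  # serialized Structured Query JSON
    cql_text: str
    issued_at: str  # ISO-8601 timestamp

    def to_json_dict(self) -> dict:
        return {
            "queryId": self.query_id,
            "structuredQuery": self.structured_query,
            "cqlText": self.cql_text,
            "issuedAt": self.issued_at,
        }


@dataclass(frozen=True)
class SiteResult:
    """One site's answer: status plus, when ok, only the obfuscated count."""

    site_id: str
    status: str  # ok | timeout | error
    obfuscated_count: Optional[ObfuscatedCount] = None
    message: str = ""

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.obfuscated_count is not None):
            raise ValueError("obfuscatedCount must be present iff status is ok")

    def to_json_dict(self) -> dict:
        out: dict = {"siteId": self.site_id, "status": self.status}
        if self.obfuscated_count is not None:
            out["obfuscatedCount"] = self.obfuscated_count.value
        if self.message:
            out["message"] = self.message
        return out


class Site:
    """One data integration center: a local store and a configured query path."""

    def __init__(
        self,
        site_id: str,
        store: ResourceStore,
        tree: TermTree,
        mapping: MappingTable,
        execution_path: str = "fhir-search",
        chunk_size: int = DEFAULT_CHUNK_SIZE,
    ):
        if execution_path not in EXECUTION_PATHS:
            if execution_path == "cql":
                raise ConfigurationError(
                    f"site {site_id!r}: the 'cql' execution path is carried in the envelope "
                    "but no CQL engine is bundled; configure 'fhir-search'"
                )
            raise ConfigurationError(
                f"site {site_id!r}: unknown execution path {execution_path!r}; "
                f"supported: {', '.join(EXECUTION_PATHS)}"
            )
        self.site_id = site_id
        self.store = store
        self.tree = tree
        self.mapping = mapping
        self.execution_path = execution_path
        self.chunk_size = chunk_size

    def answer(self, envelope: QueryEnvelope) -> ObfuscatedCount:
        """Execute the pulled envelope locally; only the obfuscated count escapes."""
        q = parse_structured_query(envelope.structured_query)
        result = count_query(q, self.store, self.tree, self.mapping, self.chunk_size)
        return obfuscate(result.patient_count)


class Broker:
    """Holds the pending envelope; sites poll it (pull, never push)."""

    def __init__(self, envelope: QueryEnvelope):
        self._envelope = envelope
        self.pulls: list[str] = []

    def poll(self, site_id: str) -> QueryEnvelope:
        self.pulls.append(site_id)
        return self._envelope


def make_envelope(
    q: StructuredQuery,
    tree: TermTree,
    mapping: MappingTable,
    query_id: str = "q-1",
    issued_at: Optional[str] = None,
) -> QueryEnvelope:
    """Derive both query representations from the same Structured Query."""
    if issued_at is None:
        issued_at = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    return QueryEnvelope(
        query_id=query_id,
        structured_query=serialize_structured_query(q),
        cql_text=translate_to_cql(q, tree, mapping),
        issued_at=issued_at,
    )


def broadcast(
    envelope: QueryEnvelope,
    sites: Sequence[Site],
    timeout_seconds: float = 300.0,
) -> list[SiteResult]:
    """Let every registered site pull and answer the envelope.

    Returns exactly one :class:`SiteResult` per site, ordered by site id.
    A site whose execution raises reports ``error``; one exceeding the
    timeout reports ``timeout``; failures are isolated — they never affect
    another site's result.
    """
    if not sites:
        raise ConfigurationError("no sites registered in the network")
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate site ids: {sorted(ids)}")

    broker = Broker(envelope)
    results: list[SiteResult] = []
    for site in sorted(sites, key=lambda s: s.site_id):
        started = time.monotonic()
        try:
            pulled = broker.poll(site.site_id)
            count = site.answer(pulled)
        except Exception as exc:
            results.append(SiteResult(site.site_id, "error", message=type(exc).__name__))
            continue
        if time.monotonic() - started > timeout_seconds:
            results.append(SiteResult(site.site_id, "timeout"))
        else:
            results.append(SiteResult(site.site_id, "ok", count))
    return results


def summarize(results: Sequence[SiteResult]) -> dict:
    """Central report: per-site obfuscated counts and their sum.

    The total is the sum of ok counts; when any site is not ok it is
    flagged ``partial`` — a lower bound, not the network-wide answer.
    """
    ok = [r for r in results if r.status == "ok"]
    report = {
        "sites": [r.to_json_dict() for r in results],
        "total": sum(r.obfuscated_count.value for r in ok),
        "sitesOk": len(ok),
        "sitesTimeout": sum(1 for r in results if r.status == "timeout"),
        "sitesError": sum(1 for r in results if r.status == "error"),
    }
    report["partial"] = report["sitesOk"] < len(results)
    return report


def load_network(
    config_path: str | Path,
    tree: TermTree,
    mapping: MappingTable,
) -> tuple[list[Site], float]:
    """Build sites from a network config JSON.

    Config shape: ``{"sites": [{"siteId", "dataPath", "executionPath"}],
    "timeoutSeconds": <float>}``; ``dataPath`` is an NDJSON resource file
    relative to the config file's directory.
    """
    path = Path(config_path)
    raw = json.loads(path.read_text(encoding="utf-8"))
    entries = raw.get("sites", [])
    if not entries:
        raise ConfigurationError(f"{path}: no sites configured")
    sites = []
    for entry in entries:
        data_path = Path(entry["dataPath"])
        if not data_path.is_absolute():
            data_path = path.parent / data_path
        store = ResourceStore.load(data_path, format="ndjson")
        sites.append(
            Site(
                site_id=entry["siteId"],
                store=store,
                tree=tree,
                mapping=mapping,
                execution_path=entry.get("executionPath", "fhir-search"),
            )
        )
    return sites, float(raw.get("timeoutSeconds", 300.0))
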