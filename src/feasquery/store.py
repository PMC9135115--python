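"""In-memory FHIR R4 resource store with a FHIR Search subset evaluator.

Stands in for the hospital FHIR server: it loads Patient, Condition,
Procedure, and Observation resources from NDJSON or a collection Bundle,
indexes their token-searchable fields, and answers exactly the FHIR
Search subset the translator emits —

* token parameters (``code``, ``gender``) with comma-OR semantics,
* quantity parameters (``value-quantity``) with ``gt/ge/lt/le/eq``
  prefixes and unit/system equality when given in the token,
* date parameters (``recorded-date``, ``date``) with inclusive ``ge``/
  ``le`` prefixes at day precision.

Any parameter outside this subset raises :class:`UnsupportedSearch`;
ignoring a parameter silently would inflate cohort counts.  Quantity
``eq`` is exact decimal comparison, a documented simplification of
FHIR's significant-digit rule.
"""

from __future__ import annotations

import datetime
import json
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union
from urllib.parse import unquote

from feasquery.fhir_search import AtomicQuery

__all__ = ["ResourceStore", "UnsupportedSearch", "StoreError", "patient_ids"]

Resource = dict

#: (resourceType, searchParameter) -> (kind, resource field path)
_SEARCH_PARAMS: dict[tuple[str, str], tuple[str, str]] = {
    ("Patient", "gender"): ("token-code", "gender"),
    ("Condition", "code"): ("token-coding", "code"),
    ("Condition", "recorded-date"): ("date", "recordedDate"),
    ("Procedure", "code"): ("token-coding", "code"),
    ("Procedure", "date"): ("date", "performedDateTime"),
    ("Observation", "code"): ("token-coding", "code"),
    ("Observation", "value-quantity"): ("quantity", "valueQuantity"),
    ("Observation", "date"): ("date", "effectiveDateTime"),
}

_SUPPORTED_TYPES = ("Patient", "Condition", "Procedure", "Observation")


class StoreError(ValueError):
    """A resource violates the store's integrity rules."""


class UnsupportedSearch(ValueError):
    """An atomic query uses a parameter outside the supported subset."""


def _date_of(value: str) -> datetime.date:
    # day precision: truncate any time-of-day component
    return datetime.date.fromisoformat(value[:10])


class ResourceStore:
    """Typed, indexed collection of FHIR resources.

    Token-searchable fields are indexed at insertion; quantity and date
    parameters are evaluated by filtering (they only ever narrow a
    token-selected candidate set in the emitted query subset).
    """

    def __init__(self) -> None:
        self._resources: dict[str, dict[str, Resource]] = {t: {} for t in _SUPPORTED_TYPES}
        # (type, param) -> token -> set of resource ids
        self._token_index: dict[tuple[str, str], dict[str, set[str]]] = {}
        self.skipped: int = 0  # unknown-type resources skipped at load

    # -- population ---------------------------------------------------------

    def add(self, resource: Resource) -> None:
        rtype = resource.get("resourceType")
        if rtype not in self._resources:
            self.skipped += 1
            return
        rid = resource.get("id")
        if not rid:
            raise StoreError(f"{rtype} resource without id")
        if rid in self._resources[rtype]:
            raise StoreError(f"duplicate {rtype} id {rid!r}")
        self._resources[rtype][rid] = resource
        self._index(rtype, rid, resource)

    def _index(self, rtype: str, rid: str, resource: Resource) -> None:
        for (ptype, param), (kind, fhir_path) in _SEARCH_PARAMS.items():
            if ptype != rtype or not kind.startswith("token"):
                continue
            bucket = self._token_index.setdefault((rtype, param), {})
            if kind == "token-code":
                value = resource.get(fhir_path)
                if value is not None:
                    bucket.setdefault(str(value), set()).add(rid)
            else:  # token-coding
                for coding in resource.get(fhir_path, {}).get("coding", []):
                    system, code = coding.get("system"), coding.get("code")
                    if code is None:
                        continue
                    bucket.setdefault(code, set()).add(rid)
                    if system is not None:
                        bucket.setdefault(f"{system}|{code}", set()).add(rid)

    def extend(self, resources: Iterable[Resource]) -> None:
        for r in resources:
            self.add(r)

    # -- introspection ------------------------------------------------------

    def count(self, resource_type: Optional[str] = None) -> int:
        if resource_type is not None:
            return len(self._resources.get(resource_type, {}))
        return sum(len(v) for v in self._resources.values())

    def counts_by_type(self) -> dict[str, int]:
        return {t: len(v) for t, v in self._resources.items()}

    def resources(self, resource_type: str) -> list[Resource]:
        return list(self._resources.get(resource_type, {}).values())

    def iter_resources(self) -> Iterator[Resource]:
        for rtype in _SUPPORTED_TYPES:
            yield from self._resources[rtype].values()

    def get(self, resource_type: str, rid: str) -> Optional[Resource]:
        return self._resources.get(resource_type, {}).get(rid)

    def validate_references(self) -> None:
        """Strict mode: every clinical resource's subject must resolve to a Patient."""
        patients = self._resources["Patient"]
        for rtype in ("Condition", "Procedure", "Observation"):
            for rid, resource in self._resources[rtype].items():
                pid = _subject_id(resource)
                if pid not in patients:
                    raise StoreError(f"{rtype}/{rid} references missing Patient/{pid}")

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_resources(cls, resources: Iterable[Resource], lenient: bool = False) -> "ResourceStore":
        store = cls()
        store.extend(resources)
        if not lenient:
            store.validate_references()
        return store

    @classmethod
    def load(cls, path: Union[str, Path], format: str = "ndjson", lenient: bool = False) -> "ResourceStore":
        """Load from NDJSON (one resource per line) or a FHIR collection Bundle."""
        text = Path(path).read_text(encoding="utf-8")
        if format == "ndjson":
            resources = (json.loads(line) for line in text.splitlines() if line.strip())
        elif format == "bundle":
            bundle = json.loads(text)
            if bundle.get("resourceType") != "Bundle":
                raise StoreError("not a FHIR Bundle")
            resources = (entry["resource"] for entry in bundle.get("entry", []))
        else:
            raise ValueError(f"unknown format {format!r}; expected 'ndjson' or 'bundle'")
        return cls.from_resources(resources, lenient=lenient)

    def to_ndjson(self) -> str:
        lines = [json.dumps(r, ensure_ascii=False, sort_keys=True) for r in self.iter_resources()]
        return "\n".join(lines) + ("\n" if lines else "")

    def to_bundle(self) -> dict:
        return {
            "resourceType": "Bundle",
            "type": "collection",
            "entry": [{"resource": r} for r in self.iter_resources()],
        }

    def save(self, path: Union[str, Path], format: str = "ndjson") -> None:
        if format == "ndjson":
            Path(path).write_text(self.to_ndjson(), encoding="utf-8")
        elif format == "bundle":
            Path(path).write_text(json.dumps(self.to_bundle(), ensure_ascii=False), encoding="utf-8")
        else:
            raise ValueError(f"unknown format {format!r}")

    # -- search --------------------------------------------------------------

    def search(self, q: AtomicQuery) -> list[Resource]:
        """Evaluate one atomic query: AND across parameters, OR within a comma list.

        Pure — the store is not modified and repeated calls return
        identical results in deterministic (insertion) order.
        """
        rtype = q.resource_type
        if rtype not in self._resources:
            raise UnsupportedSearch(f"unsupported resource type {rtype!r}")
        candidates: Optional[set[str]] = None
        filters: list[tuple[str, str, list[str]]] = []

        for name, raw_value in q.parameters:
            spec = _SEARCH_PARAMS.get((rtype, name))
            if spec is None:
                raise UnsupportedSearch(f"unsupported search parameter {rtype}?{name}")
            kind, fhir_path = spec
            tokens = [unquote(tok) for tok in raw_value.split(",")]
            if kind.startswith("token"):
                index = self._token_index.get((rtype, name), {})
                matched: set[str] = set()
                for token in tokens:
                    if kind == "token-code" and "|" in token:
                        # resource field is a bare code; match on the code part
                        token = token.rsplit("|", 1)[1]
                    matched |= index.get(token, set())
                candidates = matched if candidates is None else candidates & matched
            else:
                filters.append((kind, fhir_path, tokens))

        pool = self._resources[rtype]
        ids = pool.keys() if candidates is None else candidates
        out = []
        for rid in pool:  # insertion order for determinism
            if rid not in ids:
                continue
            resource = pool[rid]
            if all(
                any(_match_scalar(kind, resource.get(path), tok) for tok in tokens)
                for kind, path, tokens in filters
            ):
                out.append(resource)
        return out


def _match_scalar(kind: str, value, token: str) -> bool:
    if value is None:
        return False
    if kind == "date":
        prefix, datestr = token[:2], token[2:]
        if prefix not in ("ge", "le"):
            raise UnsupportedSearch(f"unsupported date prefix in {token!r}")
        have, want = _date_of(str(value)), _date_of(datestr)
        return have >= want if prefix == "ge" else have <= want
    if kind == "quantity":
        return _match_quantity(value, token)
    raise UnsupportedSearch(f"unsupported parameter kind {kind!r}")  # pragma: no cover


_QUANTITY_OPS = {
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "eq": lambda a, b: a == b,
}


def _match_quantity(quantity: dict, token: str) -> bool:
    prefix = token[:2]
    op = _QUANTITY_OPS.get(prefix)
    if op is None:
        raise UnsupportedSearch(f"unsupported quantity prefix in {token!r}")
    parts = token[2:].split("|")
    try:
        want = Decimal(parts[0])
    except InvalidOperation as exc:
        raise UnsupportedSearch(f"malformed quantity token {token!r}") from exc
    value = quantity.get("value")
    if value is None:
        return False
    have = Decimal(str(value))
    if len(parts) == 3:
        system, unit = parts[1], parts[2]
        if system and quantity.get("system") != system:
            return False
        if unit and quantity.get("unit") != unit:
            return False
    elif len(parts) != 1:
        raise UnsupportedSearch(f"malformed quantity token {token!r}")
    return op(have, want)


def _subject_id(resource: Resource) -> str:
    subject = resource.get("subject")
    if not subject or "reference" not in subject:
        raise StoreError(
            f"{resource.get('resourceType')}/{resource.get('id')} has no subject reference"
        )
    reference = subject["reference"]
    return reference.split("/", 1)[1] if reference.startswith("Patient/") else reference


def patient_ids(resources: Iterable[Resource]) -> set[str]:
    """Patient identifiers referenced by the resources (deduplicated).

    Patient resources contribute their own id; clinical resources the id of
    their subject.  A clinical resource without a subject is an error.
    """
    out: set[str] = set()
    for r in resources:
        if r.get("resourceType") == "Patient":
            out.add(r["id"])
        else:
            out.add(_subject_id(r))
    return out
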