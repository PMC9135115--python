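"""Terminology tree and FHIR mapping file.

Two configuration files drive query translation:

* the *terminology tree* — a forest of term codes capturing the concept
  hierarchy (e.g. the ICD-10 chapter structure), used to expand a selected
  parent code to itself plus all its subtypes, so that a query for
  "Diabetes mellitus, Type 2" (E11) also finds data coded E11.0, E11.1, …;
* the *mapping file* — per-concept metadata naming the FHIR resource type
  and the FHIR Search parameters with which that concept is queried.

Both are plain JSON and load losslessly.  A code missing from the tree is
not an error (it expands to itself); a code missing from the mapping is an
error at translation time — criteria must never be dropped silently.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Literal, Optional, Union

from pydantic import Field, model_validator

from feasquery.query_model import TermCode, _Model

__all__ = [
    "TermTreeNode",
    "TermTree",
    "MappingEntry",
    "MappingTable",
    "MappingNotFound",
    "DuplicateCodeError",
    "expand_code",
    "lookup_mapping",
]


class DuplicateCodeError(ValueError):
    """The same (system, code) occurs twice in one tree or mapping file."""


class MappingNotFound(KeyError):
    """No mapping entry exists for a term code; translation must fail loudly."""

    def __init__(self, code: TermCode):
        super().__init__(f"no FHIR mapping entry for {code}")
        self.code = code


class TermTreeNode(_Model):
    term_code: TermCode
    children: list["TermTreeNode"] = Field(default_factory=list)


class TermTree:
    """A forest of :class:`TermTreeNode` roots with O(1) subtree lookup."""

    def __init__(self, roots: list[TermTreeNode]):
        self.roots = roots
        self._by_code: dict[TermCode, TermTreeNode] = {}
        for root in roots:
            for node in _walk(root):
                if node.term_code in self._by_code:
                    raise DuplicateCodeError(f"duplicate code in terminology tree: {node.term_code}")
                self._by_code[node.term_code] = node

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: TermCode) -> bool:
        return code in self._by_code

    def find(self, code: TermCode) -> Optional[TermTreeNode]:
        return self._by_code.get(code)

    @classmethod
    def from_json(cls, text: str) -> "TermTree":
        raw = json.loads(text)
        if not isinstance(raw, list):
            raise ValueError("terminology tree file must be a JSON array of root nodes")
        return cls([TermTreeNode.model_validate(entry) for entry in raw])

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TermTree":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def to_json(self) -> str:
        payload = [r.model_dump(mode="json", by_alias=True) for r in self.roots]
        return json.dumps(payload, ensure_ascii=False, indent=1)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _walk(node: TermTreeNode) -> Iterator[TermTreeNode]:
    yield node
    for child in node.children:
        yield from _walk(child)


def expand_code(tree: TermTree, code: TermCode) -> list[TermCode]:
    """Expand ``code`` to itself plus all hierarchical descendants.

    Returns the codes in depth-first pre-order, the parent first: data may
    be coded at the parent level itself, so the parent is always searched
    alongside its subtypes.  A code absent from the tree has no known
    subtypes and expands to ``[code]``.
    """
    node = tree.find(code)
    if node is None:
        return [code]
    return [n.term_code for n in _walk(node)]


class MappingEntry(_Model):
    """How one concept is searched for in a FHIR server.

    ``termCodeSearchParameter`` is the token parameter carrying the concept
    code itself (``code`` for clinical resources, ``gender`` for the
    administrative-gender pseudo-concept on Patient);
    ``valueSearchParameter`` and ``timeRestrictionParameter`` name the
    parameters for value filters and time windows, when supported.
    """

    key: TermCode
    fhir_resource_type: str = Field(min_length=1)
    term_code_search_parameter: Optional[str] = None
    value_search_parameter: Optional[str] = None
    time_restriction_parameter: Optional[str] = None
    #: How the concept token is rendered: "system-code" -> ``system|code``
    #: (the collision-safe default), "code" -> bare code, used for value-set
    #: style parameters such as Patient.gender where servers expect
    #: ``gender=female``.
    token_form: Literal["system-code", "code"] = "system-code"

    @model_validator(mode="after")
    def _searchable(self) -> "MappingEntry":
        if self.term_code_search_parameter is None and self.fhir_resource_type != "Patient":
            raise ValueError(f"mapping for {self.key} lacks termCodeSearchParameter")
        return self


class MappingTable:
    """The mapping file: a dict from (system, code) to its entry."""

    def __init__(self, entries: list[MappingEntry]):
        self.entries = entries
        self._by_key: dict[TermCode, MappingEntry] = {}
        for entry in entries:
            if entry.key in self._by_key:
                raise DuplicateCodeError(f"duplicate key in mapping file: {entry.key}")
            self._by_key[entry.key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: TermCode) -> bool:
        return code in self._by_key

    def get(self, code: TermCode) -> Optional[MappingEntry]:
        return self._by_key.get(code)

    @classmethod
    def from_json(cls, text: str) -> "MappingTable":
        raw = json.loads(text)
        if not isinstance(raw, list):
            raise ValueError("mapping file must be a JSON array of entries")
        return cls([MappingEntry.model_validate(entry) for entry in raw])

    @classmethod
    def load(cls, path: Union[str, Path]) -> "MappingTable":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def to_json(self) -> str:
        payload = [e.model_dump(mode="json", by_alias=True, exclude_none=True) for e in self.entries]
        return json.dumps(payload, ensure_ascii=False, indent=1)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def lookup_mapping(mapping: MappingTable, code: TermCode) -> MappingEntry:
    """Resolve the mapping entry for ``code`` or raise :class:`MappingNotFound`."""
    entry = mapping.get(code)
    if entry is None:
        raise MappingNotFound(code)
    return entry
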