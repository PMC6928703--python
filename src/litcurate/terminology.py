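"""Controlled-vocabulary store and salient term identification (STI).

The store emulates a SNOMED-CT/UMLS-style terminology: each concept has a
preferred name, synonyms, semantic types, an entity type and parent links.
STI matches a surface term against the vocabulary and scores the match:
an exact match on a preferred name weighs 1.0, while synonym and partial
matches weigh 0.5.  Matching is purely surface-level — names are normalized
(lowercase, punctuation stripped) but never stemmed, since vocabulary names
are surface forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

from ._text import normalize

__all__ = [
    "Concept",
    "MatchLevel",
    "TermMatch",
    "TerminologyStore",
    "TerminologyError",
    "load_terminology",
    "sti_match",
    "parent_concepts",
]

#: STI weights per match level.
MATCH_WEIGHTS = {"exact": 1.0, "synonym": 0.5, "partial": 0.5, "none": 0.0}

#: Minimum length of a shared token for a partial match to count.
MIN_PARTIAL_TOKEN_LEN = 4


class TerminologyError(ValueError):
    """Malformed or inconsistent terminology content."""


class MatchLevel(str, Enum):
    EXACT = "exact"
    PARTIAL = "partial"
    SYNONYM = "synonym"
    NONE = "none"


@dataclass(frozen=True)
class Concept:
    """A controlled-vocabulary entry."""

    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    semantic_types: tuple[str, ...] = ()
    entity_type: str = ""
    parent_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.preferred_name:
            raise TerminologyError(f"concept {self.concept_id!r}: empty preferred name")


@dataclass(frozen=True)
class TermMatch:
    """Result of matching a surface term against the store."""

    surface_term: str
    concept_id: Optional[str]
    match_level: MatchLevel
    weight: float

    def __post_init__(self) -> None:
        expected = MATCH_WEIGHTS[self.match_level.value]
        if self.weight != expected:
            raise ValueError(
                f"match level {self.match_level.value} requires weight {expected}"
            )
        if self.match_level is MatchLevel.NONE and self.concept_id is not None:
            raise ValueError("a non-match cannot carry a concept id")


@dataclass
class TerminologyStore:
    """In-memory concept vocabulary with a normalized name index."""

    concepts: dict[str, Concept] = field(default_factory=dict)
    # normalized name -> list of (concept_id, original name, is_preferred)
    name_index: dict[str, list[tuple[str, str, bool]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise TerminologyError(f"duplicate concept id {concept.concept_id!r}")
        self.concepts[concept.concept_id] = concept
        self._index_name(concept.preferred_name, concept.concept_id, True)
        for syn in concept.synonyms:
            self._index_name(syn, concept.concept_id, False)

    def _index_name(self, name: str, concept_id: str, preferred: bool) -> None:
        norm = normalize(name)
        if norm:
            self.name_index.setdefault(norm, []).append((concept_id, name, preferred))

    def get(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise KeyError(f"unknown concept id {concept_id!r}") from None

    def validate(self) -> None:
        """Check referential integrity of parent links."""
        for concept in self.concepts.values():
            for pid in concept.parent_ids:
                if pid not in self.concepts:
                    raise TerminologyError(
                        f"concept {concept.concept_id!r}: dangling parent {pid!r}"
                    )


def _concept_from_record(rec: dict, where: str) -> Concept:
    try:
        return Concept(
            concept_id=str(rec["id"]),
            preferred_name=str(rec["name"]),
            synonyms=tuple(rec.get("synonyms", [])),
            semantic_types=tuple(rec.get("semantic_types", [])),
            entity_type=str(rec.get("entity_type", "")),
            parent_ids=tuple(rec.get("parents", [])),
        )
    except KeyError as exc:
        raise TerminologyError(f"{where}: missing field {exc}") from None


def load_terminology(path: Union[str, Path]) -> TerminologyStore:
    """Load a JSON terminology fixture into an indexed store.

    The file is a JSON array of objects with fields ``id``, ``name``,
    ``synonyms``, ``semantic_types``, ``entity_type`` and ``parents``.
    Duplicate ids and dangling parent links are rejected.
    """
    path = Path(path)
    try:
        records = json.loads(path.read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise TerminologyError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(records, list):
        raise TerminologyError(f"{path}: expected a JSON array of concepts")
    return build_store(
        _concept_from_record(rec, f"{path} record {i}") for i, rec in enumerate(records)
    )


def build_store(concepts: Iterable[Concept]) -> TerminologyStore:
    store = TerminologyStore()
    for concept in concepts:
        store.add(concept)
    store.validate()
    return store


def _best_candidate(
    candidates: list[tuple[str, str]],
) -> str:
    """Pick a concept id from (concept_id, matched name) candidates.

    Tie-break: longest matched name first, then lexicographically smallest
    concept id.
    """
    return min(candidates, key=lambda c: (-len(c[1]), c[0]))[0]


def sti_match(
    term: str, store: TerminologyStore, partial_mode: str = "both"
) -> TermMatch:
    """Match a surface term against the store, weighted by match level.

    Precedence is exact (preferred name, w=1.0) > synonym (w=0.5) >
    partial (w=0.5).  A partial match requires the normalized term's token
    set to be a non-empty proper subset of a concept name's token set (or
    vice versa) with at least one shared token of >=4 characters.

    ``partial_mode="fragment"`` restricts partials to the term-is-fragment
    direction (term tokens a proper subset of the name's).  Scanners over
    running text use it so an arbitrary n-gram window that merely contains
    a concept name does not register as a match of that concept.
    """
    if not term:
        raise ValueError("term must be non-empty")
    if partial_mode not in ("both", "fragment"):
        raise ValueError(f"unknown partial_mode {partial_mode!r}")
    norm = normalize(term)

    entries = store.name_index.get(norm, ())
    exact = [(cid, name) for cid, name, pref in entries if pref]
    if exact:
        return TermMatch(term, _best_candidate(exact), MatchLevel.EXACT, 1.0)
    synonyms = [(cid, name) for cid, name, pref in entries if not pref]
    if synonyms:
        return TermMatch(term, _best_candidate(synonyms), MatchLevel.SYNONYM, 0.5)

    term_tokens = set(norm.split())
    if term_tokens:
        partial: list[tuple[str, str]] = []
        for indexed_norm, indexed in store.name_index.items():
            name_tokens = set(indexed_norm.split())
            if term_tokens == name_tokens:
                continue
            subset = term_tokens < name_tokens or (
                partial_mode == "both" and name_tokens < term_tokens
            )
            shared = term_tokens & name_tokens
            if subset and shared and any(len(t) >= MIN_PARTIAL_TOKEN_LEN for t in shared):
                partial.extend((cid, name) for cid, name, _pref in indexed)
        if partial:
            return TermMatch(term, _best_candidate(partial), MatchLevel.PARTIAL, 0.5)

    return TermMatch(term, None, MatchLevel.NONE, 0.0)


def parent_concepts(concept_id: str, store: TerminologyStore) -> list[Concept]:
    """One-level parent lookup, in fixture order."""
    concept = store.get(concept_id)
    return [store.get(pid) for pid in concept.parent_ids]
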