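"""Construction of well-built PICO questions.

Three input routes are supported:

* free clinical text — tokenized, stopword-filtered, lowercased and
  Porter-stemmed for candidate detection; candidate n-grams (n <= 4) are
  matched against the terminology with STI and slotted by semantic/entity
  type;
* pre-labeled structured records — slots pass through, with STI used only
  for standardization;
* CDSS knowledge rules — the rule's data elements map to P, its action
  elements to I and C (first action to I, the rest to C), and its purpose,
  when present, to O.

The query type (diagnosis / treatment / prognosis / etiology) is inferred
from the parents of the I and C concepts via a translation table, by
majority vote.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

from ._text import normalize, porter_stem, stopwords
from .terminology import Concept, TerminologyStore, parent_concepts, sti_match

__all__ = [
    "Slot",
    "QueryType",
    "WeightedTerm",
    "PicoQuestion",
    "KnowledgeRule",
    "pico_from_text",
    "pico_from_structured",
    "pico_from_rule",
    "assign_slot",
    "identify_query_type",
    "default_slot_mapping",
    "default_translation_table",
]

MAX_NGRAM = 4

#: Fixed tie priority for query-type majority votes.
QUERY_TYPE_PRIORITY = ("treatment", "diagnosis", "prognosis", "etiology")


class Slot(str, Enum):
    P = "P"
    I = "I"
    C = "C"
    O = "O"


class QueryType(str, Enum):
    DIAGNOSIS = "diagnosis"
    TREATMENT = "treatment"
    PROGNOSIS = "prognosis"
    ETIOLOGY = "etiology"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class WeightedTerm:
    surface: str
    concept_id: Optional[str]
    weight: float
    slot: Slot


@dataclass
class PicoQuestion:
    """Slotted P/I/C/O weighted terms plus the inferred query purpose."""

    p_terms: list[WeightedTerm] = field(default_factory=list)
    i_terms: list[WeightedTerm] = field(default_factory=list)
    c_terms: list[WeightedTerm] = field(default_factory=list)
    o_terms: list[WeightedTerm] = field(default_factory=list)
    query_type: QueryType = QueryType.UNKNOWN

    def slot_terms(self, slot: Slot) -> list[WeightedTerm]:
        return {
            Slot.P: self.p_terms,
            Slot.I: self.i_terms,
            Slot.C: self.c_terms,
            Slot.O: self.o_terms,
        }[slot]

    @property
    def all_terms(self) -> list[WeightedTerm]:
        return self.p_terms + self.i_terms + self.c_terms + self.o_terms

    @property
    def searchable(self) -> bool:
        """P and I are the core of a well-built question."""
        return bool(self.p_terms or self.i_terms)

    def add(self, term: WeightedTerm) -> None:
        existing = {normalize(t.surface) for t in self.all_terms}
        if normalize(term.surface) in existing:
            return
        self.slot_terms(term.slot).append(term)


@dataclass(frozen=True)
class KnowledgeRule:
    """Pre-extracted elements of a CDSS knowledge rule.

    ``data_elements`` are the rule's data/condition part, ``action_elements``
    its action part, and ``purpose`` the intent it was authored for.  Full
    Arden-syntax MLM parsing is out of scope — elements arrive pre-extracted.
    """

    data_elements: tuple[str, ...]
    action_elements: tuple[str, ...] = ()
    purpose: Optional[str] = None
    scheme: str = "production_rule"

    def __post_init__(self) -> None:
        if self.scheme not in ("production_rule", "mlm"):
            raise ValueError(f"unknown rule scheme {self.scheme!r}")


def _load_json_resource(name: str) -> dict:
    raw = resources.files("litcurate.data").joinpath(name).read_text("utf-8")
    return json.loads(raw)


@lru_cache(maxsize=1)
def default_slot_mapping() -> dict:
    return _load_json_resource("slot_mapping.json")


@lru_cache(maxsize=1)
def default_translation_table() -> dict:
    return _load_json_resource("query_type_translation.json")


def assign_slot(
    concept: Concept,
    mapping: Optional[Mapping] = None,
    *,
    intervention_seen: bool = False,
) -> Slot:
    """Map a concept to a PICO slot via its semantic/entity types.

    Semantic types are checked first, then the entity type.  Intervention-
    class concepts go to I the first time and to C afterwards (the caller
    tracks ``intervention_seen``).  Types not covered by the mapping fall
    back to P with a warning rather than dropping a matched concept.
    """
    mapping = mapping or default_slot_mapping()
    raw: Optional[str] = None
    for st in concept.semantic_types:
        raw = mapping.get("semantic_types", {}).get(normalize(st))
        if raw:
            break
    if raw is None and concept.entity_type:
        raw = mapping.get("entity_types", {}).get(normalize(concept.entity_type))
    if raw is None:
        warnings.warn(
            f"concept {concept.concept_id!r} ({concept.preferred_name!r}) has no "
            f"slot mapping; defaulting to P",
            stacklevel=2,
        )
        raw = mapping.get("fallback", "P")
    if raw == "I" and intervention_seen:
        return Slot.C
    return Slot(raw)


def _candidate_grams(text: str) -> list[str]:
    """Stopword-filtered surface tokens, ready for n-gram matching.

    Edge punctuation is stripped (inner hyphens survive) so matched
    surfaces render cleanly in queries.
    """
    import string

    stops = stopwords()
    tokens = []
    for tok in text.split():
        tok = tok.strip(string.punctuation)
        if tok and normalize(tok) and normalize(tok) not in stops:
            tokens.append(tok)
    return tokens


def pico_from_text(
    text: str,
    store: TerminologyStore,
    *,
    slot_mapping: Optional[Mapping] = None,
    translation: Optional[Mapping] = None,
) -> PicoQuestion:
    """Build a PICO question from free clinical text.

    Tokens are matched greedily as n-grams (longest first, n <= 4); each
    matched concept is slotted once.  The stemmed form of a matched phrase
    is tracked so repeated surface variants of the same phrase are not
    slotted twice.  If nothing matches, an empty (unsearchable) question is
    returned rather than raising.
    """
    if not text:
        raise ValueError("text must be non-empty")
    tokens = _candidate_grams(text)

    question = PicoQuestion()
    seen_concepts: set[str] = set()
    seen_stems: set[str] = set()
    intervention_seen = False

    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(MAX_NGRAM, len(tokens) - i), 0, -1):
            gram = " ".join(tokens[i : i + n])
            stem_key = " ".join(porter_stem(t) for t in normalize(gram).split())
            if stem_key in seen_stems:
                i += n
                matched = True
                break
            match = sti_match(gram, store, partial_mode="fragment")
            if match.weight > 0.0 and match.concept_id not in seen_concepts:
                concept = store.get(match.concept_id)
                slot = assign_slot(
                    concept, slot_mapping, intervention_seen=intervention_seen
                )
                if slot in (Slot.I, Slot.C):
                    intervention_seen = True
                question.add(
                    WeightedTerm(gram, match.concept_id, match.weight, slot)
                )
                seen_concepts.add(match.concept_id)
                seen_stems.add(stem_key)
                i += n
                matched = True
                break
        if not matched:
            i += 1

    question.query_type = identify_query_type(question, store, translation)
    return question


def pico_from_structured(
    record: Mapping[str, Sequence[str]],
    store: Optional[TerminologyStore] = None,
) -> PicoQuestion:
    """Accept a pre-labeled record (problem/intervention/comparison/outcome).

    Labels pass through to the corresponding slots; when a store is given,
    each term is run through STI for standardization so its weight and
    concept id are attached.
    """
    slot_keys = {
        "problem": Slot.P,
        "intervention": Slot.I,
        "comparison": Slot.C,
        "outcome": Slot.O,
    }
    question = PicoQuestion()
    for key, slot in slot_keys.items():
        for surface in record.get(key, []):
            if store is not None:
                match = sti_match(surface, store)
                weight = match.weight if match.weight > 0 else 1.0
                cid = match.concept_id
            else:
                weight, cid = 1.0, None
            question.add(WeightedTerm(surface, cid, weight, slot))
    if store is not None:
        question.query_type = identify_query_type(question, store)
    return question


def pico_from_rule(rule: KnowledgeRule) -> PicoQuestion:
    """Map a knowledge rule onto PICO.

    Data elements become P terms, the first action element becomes the I
    term and the remaining actions the C terms, and the rule's purpose (if
    any) becomes the O term.  Production rules commonly have no purpose, in
    which case O stays unmapped.
    """
    if not rule.data_elements:
        raise ValueError("rule must have at least one data element")
    question = PicoQuestion()
    for d in rule.data_elements:
        question.add(WeightedTerm(d, None, 1.0, Slot.P))
    for k, a in enumerate(rule.action_elements):
        question.add(WeightedTerm(a, None, 1.0, Slot.I if k == 0 else Slot.C))
    if rule.purpose:
        question.add(WeightedTerm(rule.purpose, None, 1.0, Slot.O))
    return question


def identify_query_type(
    question: PicoQuestion,
    store: TerminologyStore,
    translation: Optional[Mapping] = None,
) -> QueryType:
    """Infer the query purpose from parents of the I and C concepts.

    Each parent is translated (by normalized name, falling back to its
    semantic types) to a purpose; the majority vote wins and ties resolve
    by the fixed priority treatment > diagnosis > prognosis > etiology.
    No vote yields ``unknown``.
    """
    translation = translation or default_translation_table()
    votes: Counter[str] = Counter()
    for term in question.i_terms + question.c_terms:
        if term.concept_id is None or term.concept_id not in store:
            continue
        for parent in parent_concepts(term.concept_id, store):
            translated = translation.get(normalize(parent.preferred_name))
            if translated is None:
                for st in parent.semantic_types:
                    translated = translation.get(normalize(st))
                    if translated:
                        break
            if translated:
                votes[translated] += 1
    if not votes:
        return QueryType.UNKNOWN
    top = max(votes.values())
    for qt in QUERY_TYPE_PRIORITY:
        if votes.get(qt) == top:
            return QueryType(qt)
    return QueryType.UNKNOWN
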