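"""Boolean query construction, rendering and retrieval-driven optimization.

A PICO question renders to a conjunction of groups: every P term is its own
AND-group, the I and C terms together form one OR-group (an intervention and
its comparator are interchangeable retrieval-wise), and each O term is a
trailing AND-group.  When a query retrieves too few results it is relaxed by
dropping one term at a time — comparison terms first, then outcome terms,
then the lowest-STI-weight term of the P/I core — until the result threshold
is met or a single term remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Optional, Protocol, Sequence

from .pico_builder import PicoQuestion, QueryType, Slot, WeightedTerm

__all__ = [
    "BooleanQuery",
    "SearchOutcome",
    "SearchBackend",
    "BackendError",
    "build_query",
    "optimize_query",
    "render_query",
    "default_clinical_filters",
]


@dataclass
class BooleanQuery:
    """Conjunction of disjunction-groups over weighted terms."""

    and_groups: list[list[WeightedTerm]] = field(default_factory=list)
    clinical_filter: Optional[QueryType] = None

    @property
    def terms(self) -> list[WeightedTerm]:
        return [t for group in self.and_groups for t in group]

    def copy(self) -> "BooleanQuery":
        return BooleanQuery(
            [list(group) for group in self.and_groups], self.clinical_filter
        )


@dataclass(frozen=True)
class SearchOutcome:
    article_ids: tuple[str, ...]
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count < len(self.article_ids):
            raise ValueError("total_count cannot undercount returned ids")


class SearchBackend(Protocol):
    """Contract a literature search service must satisfy."""

    def search(self, query: BooleanQuery) -> SearchOutcome: ...

    def fetch(self, ids: Sequence[str]) -> list:  # list[ArticleRecord]
        ...


class BackendError(RuntimeError):
    """Search transport failure; carries the query that was attempted."""

    def __init__(self, message: str, query: Optional[BooleanQuery] = None):
        super().__init__(message)
        self.query = query


@lru_cache(maxsize=1)
def default_clinical_filters() -> dict[str, str]:
    raw = resources.files("litcurate.data").joinpath("clinical_filters.json")
    return json.loads(raw.read_text("utf-8"))


def build_query(question: PicoQuestion) -> BooleanQuery:
    """Render a PICO question as a boolean query.

    Raises if the question is unsearchable (no P and no I terms).  The
    question's query type, when known, is attached as a clinical filter.
    """
    if not question.searchable:
        raise ValueError("unsearchable question: both P and I slots are empty")
    groups: list[list[WeightedTerm]] = [[t] for t in question.p_terms]
    ic = list(question.i_terms) + list(question.c_terms)
    if ic:
        groups.append(ic)
    groups.extend([t] for t in question.o_terms)
    clinical = question.query_type if question.query_type != QueryType.UNKNOWN else None
    return BooleanQuery(groups, clinical)


def render_query(query: BooleanQuery, dialect: str = "plain") -> str:
    """Render to a search string.

    ``plain`` joins groups with AND, parenthesizing multi-term OR-groups.
    ``pubmed`` additionally appends the clinical-queries filter clause for
    the attached query type.
    """
    if dialect not in ("plain", "pubmed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parts = []
    for group in query.and_groups:
        if not group:
            continue
        if len(group) == 1:
            parts.append(group[0].surface)
        else:
            parts.append("(" + " OR ".join(t.surface for t in group) + ")")
    rendered = " AND ".join(parts)
    if dialect == "pubmed" and query.clinical_filter is not None:
        clause = default_clinical_filters().get(query.clinical_filter.value)
        if clause:
            rendered = f"({rendered}) AND ({clause})"
    return rendered


def _removal_candidate(query: BooleanQuery) -> Optional[tuple[int, int]]:
    """Position (group index, term index) of the next term to drop.

    Order: any C term, then any O term, then the lowest-weight P/I term.
    Within a slot, ties fall to the lowest weight and then the most
    recently added occurrence.  The final remaining term is never dropped.
    """
    if len(query.terms) <= 1:
        return None
    positions = [
        (gi, ti, t)
        for gi, group in enumerate(query.and_groups)
        for ti, t in enumerate(group)
    ]
    for slot in (Slot.C, Slot.O):
        slotted = [(gi, ti, t) for gi, ti, t in positions if t.slot is slot]
        if slotted:
            gi, ti, _ = min(
                reversed(slotted), key=lambda p: p[2].weight
            )  # reversed: most recent wins weight ties
            return gi, ti
    core = [(gi, ti, t) for gi, ti, t in positions if t.slot in (Slot.P, Slot.I)]
    gi, ti, _ = min(reversed(core), key=lambda p: p[2].weight)
    return gi, ti


def optimize_query(
    query: BooleanQuery,
    backend: SearchBackend,
    min_results: int = 1,
    max_results: Optional[int] = None,
) -> tuple[BooleanQuery, SearchOutcome]:
    """Relax the query until it retrieves at least ``min_results`` articles.

    Each iteration runs the search and, if the threshold is unmet, drops
    exactly one term (C first, then O, then the weakest core term); the
    loop stops at the threshold or when one term remains.  The final query
    and its search outcome are returned; a still-empty single-term outcome
    is returned as-is for the caller to flag.
    """
    if min_results < 1:
        raise ValueError("min_results must be >= 1")
    current = query.copy()
    while True:
        try:
            outcome = backend.search(current)
        except BackendError:
            raise
        except Exception as exc:  # pragma: no cover - transport-specific
            raise BackendError(str(exc), current) from exc
        if outcome.total_count >= min_results:
            if max_results is not None and outcome.total_count > max_results:
                import warnings

                warnings.warn(
                    f"query returned {outcome.total_count} results "
                    f"(> max_results={max_results})",
                    stacklevel=2,
                )
            return current, outcome
        pos = _removal_candidate(current)
        if pos is None:
            return current, outcome
        gi, ti = pos
        del current.and_groups[gi][ti]
        if not current.and_groups[gi]:
            del current.and_groups[gi]


def question_from_query(query: BooleanQuery) -> PicoQuestion:
    """Reconstruct a PICO view of a (possibly optimized) query."""
    q = PicoQuestion()
    for term in query.terms:
        q.add(replace(term))
    if query.clinical_filter is not None:
        q.query_type = query.clinical_filter
    return q
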