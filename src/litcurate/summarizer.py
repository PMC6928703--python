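"""Triage and extractive PIO summarization of retrieved articles.

Secondary studies (systematic reviews, meta-analyses) already synthesize
primary evidence, so they are kept as evidence with their metadata only.
Primary studies get an extractive summary: abstract sentences are scored
per PICO element by the summed STI weights of the concepts they mention
(C counts as I — a comparator is itself an intervention), and the top
sentences per element are kept in document order.  Article summaries are
then grouped into evidence by single-linkage over Jaccard token-set
similarity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from ._text import normalize
from .article_store import ArticleRecord
from .pico_builder import Slot, assign_slot, _candidate_grams, MAX_NGRAM
from .terminology import TerminologyStore, sti_match

__all__ = [
    "StudyKind",
    "ArticleSummary",
    "triage",
    "split_sentences",
    "extract_pio",
    "summarize_article",
    "group_evidence",
]

SECONDARY_TYPES = ("systematic review", "meta-analysis", "meta analysis")

#: Abbreviations that must not terminate a sentence.
_ABBREVIATIONS = ("e.g", "i.e", "et al", "vs", "dr", "fig", "no", "approx")

DEFAULT_TOP_K = 3
DEFAULT_SCORE_THRESHOLD = 0.0


class StudyKind(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


def triage(rec: ArticleRecord) -> StudyKind:
    """Primary vs secondary; any secondary publication type dominates."""
    for pt in rec.publication_types:
        if any(sec in normalize(pt) for sec in SECONDARY_TYPES):
            return StudyKind.SECONDARY
    return StudyKind.PRIMARY


_SENTENCE_END = re.compile(r"([.!?])\s+")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting with an abbreviation guard."""
    if not text.strip():
        return []
    pieces: list[str] = []
    start = 0
    for m in _SENTENCE_END.finditer(text):
        candidate = text[start : m.end(1)].strip()
        head = candidate[:-1].rstrip().lower()
        if any(head.endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        if candidate:
            pieces.append(candidate)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return pieces


def _sentence_scores(
    sentence: str, store: TerminologyStore
) -> dict[Slot, float]:
    """Summed STI weights of matched concepts per element (C folds into I)."""
    tokens = _candidate_grams(sentence)
    scores = {Slot.P: 0.0, Slot.I: 0.0, Slot.O: 0.0}
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(MAX_NGRAM, len(tokens) - i), 0, -1):
            gram = " ".join(tokens[i : i + n])
            match = sti_match(gram, store, partial_mode="fragment")
            if match.weight > 0:
                concept = store.get(match.concept_id)
                slot = assign_slot(concept)
                if slot is Slot.C:
                    slot = Slot.I
                scores[slot] += match.weight
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return scores


def extract_pio(
    rec: ArticleRecord,
    store: TerminologyStore,
    top_k: int = DEFAULT_TOP_K,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> dict[str, list[str]]:
    """Attribute abstract sentences to the P, I and O elements.

    A sentence is attributed to every element whose score exceeds the
    threshold; at most ``top_k`` sentences per element are kept, in
    document order.  Empty text yields empty lists.
    """
    sentences = split_sentences(rec.abstract)
    per_element: dict[str, list[tuple[float, str]]] = {"P": [], "I": [], "O": []}
    for sent in sentences:
        scores = _sentence_scores(sent, store)
        for slot in (Slot.P, Slot.I, Slot.O):
            if scores[slot] > threshold:
                per_element[slot.value].append((scores[slot], sent))
    out: dict[str, list[str]] = {}
    for element, scored in per_element.items():
        keep = sorted(scored, key=lambda s: -s[0])[:top_k]
        kept = {id(s) for _, s in keep}
        out[element] = [s for _, s in scored if id(s) in kept]
    return out


@dataclass
class ArticleSummary:
    """Per-element extractive summary plus the article's meta information."""

    article_id: str
    p_sentences: list[str] = field(default_factory=list)
    i_sentences: list[str] = field(default_factory=list)
    o_sentences: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def combined(self) -> str:
        """Whole-article summary: P then I then O element summaries."""
        return " ".join(self.p_sentences + self.i_sentences + self.o_sentences)


def summarize_article(
    rec: ArticleRecord,
    store: TerminologyStore,
    top_k: int = DEFAULT_TOP_K,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> ArticleSummary:
    meta = {
        "publication_types": list(rec.publication_types),
        "year": rec.year,
        "journal": rec.journal,
    }
    if triage(rec) is StudyKind.SECONDARY:
        meta["study_kind"] = StudyKind.SECONDARY.value
        return ArticleSummary(rec.article_id, meta=meta)
    meta["study_kind"] = StudyKind.PRIMARY.value
    elements = extract_pio(rec, store, top_k, threshold)
    return ArticleSummary(
        rec.article_id, elements["P"], elements["I"], elements["O"], meta
    )


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union)


def group_evidence(
    summaries: Sequence[ArticleSummary], threshold: float = 0.5
) -> list[list[ArticleSummary]]:
    """Single-linkage grouping over combined-summary token-set similarity.

    Two summaries link when their Jaccard similarity meets the threshold;
    connected components form the evidence groups (a partition of the
    input, in first-appearance order).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    n = len(summaries)
    token_sets = [set(normalize(s.combined).split()) for s in summaries]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _jaccard(token_sets[i], token_sets[j]) >= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[ArticleSummary]] = {}
    order: list[int] = []
    for i, summary in enumerate(summaries):
        root = find(i)
        if root not in groups:
            groups[root] = []
            order.append(root)
        groups[root].append(summary)
    return [groups[r] for r in order]
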