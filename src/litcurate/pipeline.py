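"""End-to-end orchestration: input -> PICO -> query -> search -> classify
-> rank -> summarize -> JSON report.

The report is a plain, deterministically serialized dictionary so that two
runs with the same inputs, configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .article_store import read_jsonl, parse_medline_xml
from .eqrm import ModelBundle, load_bundle
from .fixtures import make_fixture_backend
from .pico_builder import (
    KnowledgeRule,
    PicoQuestion,
    pico_from_rule,
    pico_from_text,
)
from .query_engine import build_query, optimize_query, render_query
from .ranking import rank_articles
from .summarizer import group_evidence, summarize_article
from .terminology import TerminologyStore, load_terminology

__all__ = ["PipelineConfig", "UnsearchableQuestionError", "run_pipeline", "write_report"]


class UnsearchableQuestionError(ValueError):
    """No searchable PICO core could be built from the input."""

    def __init__(self, empty_slots: list[str]):
        self.empty_slots = empty_slots
        super().__init__(
            f"unsearchable question: empty slots {', '.join(empty_slots)}"
        )


@dataclass
class PipelineConfig:
    terminology_path: Union[str, Path]
    bundle_path: Union[str, Path]
    articles_path: Union[str, Path]  # MEDLINE XML or JSONL for the fixture backend
    min_results: int = 1
    summary_top_k: int = 3
    grouping_threshold: float = 0.5
    user_context: Optional[dict] = None
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "terminology": str(self.terminology_path),
                "bundle": str(self.bundle_path),
                "articles": str(self.articles_path),
                "min_results": self.min_results,
                "summary_top_k": self.summary_top_k,
                "grouping_threshold": self.grouping_threshold,
                "user_context": self.user_context,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _question_json(question: PicoQuestion) -> dict:
    from .pico_builder import Slot

    return {
        slot: [
            {"surface": t.surface, "concept_id": t.concept_id, "weight": t.weight}
            for t in question.slot_terms(Slot(slot))
        ]
        for slot in ("P", "I", "C", "O")
    } | {"query_type": question.query_type.value}


def _load_articles(path: Union[str, Path]):
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return parse_medline_xml(path)
    records, _labels = read_jsonl(path)
    return records


def run_pipeline(
    *,
    text: Optional[str] = None,
    rule: Optional[KnowledgeRule] = None,
    config: PipelineConfig,
    store: Optional[TerminologyStore] = None,
    bundle: Optional[ModelBundle] = None,
) -> dict:
    """Run the full curation flow and return the report dictionary.

    Exactly one of ``text`` or ``rule`` must be given.  Raises
    :class:`UnsearchableQuestionError` when no P or I term can be built.
    """
    if (text is None) == (rule is None):
        raise ValueError("provide exactly one of text or rule")
    store = store or load_terminology(config.terminology_path)
    bundle = bundle or load_bundle(config.bundle_path)

    question = pico_from_text(text, store) if text is not None else pico_from_rule(rule)
    if not question.searchable:
        from .pico_builder import Slot

        empty = [s for s in ("P", "I") if not question.slot_terms(Slot(s))]
        raise UnsearchableQuestionError(empty)

    query = build_query(question)
    backend = make_fixture_backend(_load_articles(config.articles_path))
    final_query, outcome = optimize_query(query, backend, config.min_results)
    articles = backend.fetch(outcome.article_ids)

    probs = bundle.score_records(articles) if articles else []
    ranked = rank_articles(
        list(zip(articles, probs)), user_context=config.user_context
    )

    summaries = {
        rec.article_id: summarize_article(
            rec, store, top_k=config.summary_top_k
        )
        for rec in articles
    }
    ordered_summaries = [summaries[r["article"].article_id] for r in ranked]
    groups = group_evidence(ordered_summaries, config.grouping_threshold)

    return {
        "pico": _question_json(question),
        "query": {
            "initial": render_query(query),
            "final": render_query(final_query),
            "pubmed": render_query(final_query, dialect="pubmed"),
            "removed_terms": len(query.terms) - len(final_query.terms),
        },
        "search": {
            "total_count": outcome.total_count,
            "article_ids": list(outcome.article_ids),
        },
        "articles": [
            {
                "article_id": r["article"].article_id,
                "title": r["article"].title,
                "grade": r["grade"].name,
                "pubtype_rank": r["pubtype_rank"],
                "rigor_probability": round(r["rigor_probability"], 6),
                "year": r["article"].year,
            }
            for r in ranked
        ],
        "evidence_groups": [
            [
                {
                    "article_id": s.article_id,
                    "summary": s.combined,
                    "meta": s.meta,
                }
                for s in group
            ]
            for group in groups
        ],
        "provenance": {
            "seed": config.seed,
            "config_digest": config.digest(),
            "backend": "fixture",
        },
    }


def write_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
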