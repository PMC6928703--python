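"""Evidence grading and cross-context ranking.

Articles are graded H (high) > M (medium) > L (low) > U (unknown).  A
publication-type table assigns each article a rank 1-11 and a grade (rank
<= 3 is H, 4-7 is M, >= 8 is L).  The cross-context step crosses user
context parameters (rows) with evidence properties (columns): each column
aggregates by majority vote (ties toward the higher grade) and the final
grade is the highest column aggregate.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache, total_ordering
from importlib import resources
from typing import Mapping, Optional, Sequence

from ._text import normalize
from .article_store import ArticleRecord

__all__ = [
    "Grade",
    "PubTypeRankTable",
    "ContextMatrix",
    "default_pubtype_table",
    "pubtype_rank",
    "aggregate_column",
    "cross_context_grade",
    "rank_articles",
]


@total_ordering
class Grade(Enum):
    U = 0
    L = 1
    M = 2
    H = 3

    def __lt__(self, other: "Grade") -> bool:
        return self.value < other.value

    @classmethod
    def parse(cls, label: str) -> "Grade":
        return cls[label.strip().upper()]


FALLBACK_ROW = "any other publication type"
FALLBACK_RANK = 11


def _grade_band(rank: int) -> Grade:
    if rank <= 3:
        return Grade.H
    if rank <= 7:
        return Grade.M
    return Grade.L


@dataclass(frozen=True)
class PubTypeRankTable:
    """Publication-type name -> (rank 1-11, grade), plus name aliases."""

    rows: tuple[tuple[str, int, Grade], ...]
    aliases: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, rank, grade in self.rows:
            if not (1 <= rank <= FALLBACK_RANK):
                raise ValueError(f"{name!r}: rank {rank} outside 1..{FALLBACK_RANK}")
            if grade is not _grade_band(rank):
                raise ValueError(
                    f"{name!r}: grade {grade.name} inconsistent with rank {rank}"
                )

    def lookup(self, pub_type: str) -> tuple[int, Grade]:
        key = normalize(pub_type)
        key = normalize(self.aliases.get(key, key))
        for name, rank, grade in self.rows:
            if normalize(name) == key:
                return rank, grade
        return FALLBACK_RANK, _grade_band(FALLBACK_RANK)


@lru_cache(maxsize=1)
def default_pubtype_table() -> PubTypeRankTable:
    raw = resources.files("litcurate.data").joinpath("pubtype_ranks.json")
    data = json.loads(raw.read_text("utf-8"))
    rows = tuple(
        (row["type"], int(row["rank"]), Grade.parse(row["grade"]))
        for row in data["table"]
    )
    return PubTypeRankTable(rows, data.get("aliases", {}))


def pubtype_rank(
    pub_types: Sequence[str], table: Optional[PubTypeRankTable] = None
) -> tuple[int, Grade]:
    """Best (minimum) rank over an article's publication types.

    Unlisted types — and the empty list — fall to the "any other" row.
    """
    table = table or default_pubtype_table()
    if not pub_types:
        return FALLBACK_RANK, _grade_band(FALLBACK_RANK)
    ranked = [table.lookup(pt) for pt in pub_types]
    return min(ranked, key=lambda rg: rg[0])


@dataclass(frozen=True)
class ContextMatrix:
    """User context rows crossed with evidence property columns."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: tuple[tuple[Grade, ...], ...]  # one tuple per row

    def __post_init__(self) -> None:
        if not self.row_labels or not self.col_labels:
            raise ValueError("matrix needs at least one row and one column")
        if len(self.cells) != len(self.row_labels) or any(
            len(r) != len(self.col_labels) for r in self.cells
        ):
            raise ValueError("cells must be rectangular and match the labels")

    def column(self, j: int) -> list[Grade]:
        return [row[j] for row in self.cells]


def aggregate_column(cells: Sequence[Grade]) -> Grade:
    """Majority vote over a column; ties break toward the higher grade."""
    if not cells:
        raise ValueError("cannot aggregate an empty column")
    counts = Counter(cells)
    top = max(counts.values())
    return max(g for g, c in counts.items() if c == top)


def cross_context_grade(matrix: ContextMatrix) -> Grade:
    """Aggregate each column, then take the highest aggregate."""
    aggregates = [
        aggregate_column(matrix.column(j)) for j in range(len(matrix.col_labels))
    ]
    return max(aggregates)


def rank_articles(
    articles: Sequence[tuple[ArticleRecord, float]],
    user_context: Optional[Mapping[str, Sequence[str]]] = None,
    table: Optional[PubTypeRankTable] = None,
) -> list[dict]:
    """Order classified articles for presentation.

    ``user_context`` maps context parameter names (education, background,
    goal, ...) to per-evidence-property grade labels; when absent, the
    article's own publication-type grade forms a 1x1 matrix.  The sort key
    is (cross-context grade desc, publication-type rank asc, rigor
    probability desc, year desc), stable for equal keys.
    """
    table = table or default_pubtype_table()
    rows = []
    for order, (rec, rigor_prob) in enumerate(articles):
        rank, type_grade = pubtype_rank(rec.publication_types, table)
        if user_context:
            row_labels = tuple(user_context.keys())
            cells = tuple(
                tuple(Grade.parse(g) for g in user_context[label])
                for label in row_labels
            )
            n_cols = len(cells[0])
            matrix = ContextMatrix(
                row_labels, tuple(f"P{j + 1}" for j in range(n_cols)), cells
            )
            grade = max(cross_context_grade(matrix), type_grade)
        else:
            grade = type_grade
        rows.append(
            {
                "article": rec,
                "grade": grade,
                "pubtype_rank": rank,
                "rigor_probability": float(rigor_prob),
                "_order": order,
            }
        )
    rows.sort(
        key=lambda r: (
            -r["grade"].value,
            r["pubtype_rank"],
            -r["rigor_probability"],
            -(r["article"].year or 0),
            r["_order"],
        )
    )
    for r in rows:
        del r["_order"]
    return rows
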