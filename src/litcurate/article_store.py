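"""MEDLINE record parsing and the two-block feature representation.

Articles are represented by data features (title + abstract tokens:
lowercased, stopword-filtered, Porter-stemmed, length-filtered) and
metadata features (MeSH terms and publication types: tokenized and
lowercased only, since controlled-vocabulary labels need neither stopword
removal nor stemming).  The two namespaces are kept disjoint by prefixing
metadata tokens.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from lxml import etree
from sklearn.feature_extraction import DictVectorizer
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.pipeline import Pipeline

from ._text import porter_stem, stopwords, tokenize

__all__ = [
    "ArticleRecord",
    "parse_medline_xml",
    "write_medline_xml",
    "data_features",
    "metadata_features",
    "combined_features",
    "vectorize_corpus",
    "CorpusVectorizer",
    "read_jsonl",
    "write_jsonl",
]

META_PREFIX = "meta::"

#: Token length bounds for data features (configurable per call).
MIN_TOKEN_LEN = 2
MAX_TOKEN_LEN = 25


@dataclass
class ArticleRecord:
    """A parsed MEDLINE-format article."""

    article_id: str
    title: str = ""
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    publication_types: list[str] = field(default_factory=list)
    journal: str = ""
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValueError("article_id must be non-empty")
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise ValueError(f"implausible year {self.year}")


def parse_medline_xml(source: Union[str, Path, bytes]) -> list[ArticleRecord]:
    """Parse a PubMed eFetch XML document into article records.

    Records lacking a PMID are skipped with a warning.  A missing abstract
    becomes the empty string.
    """
    if isinstance(source, bytes):
        try:
            root = etree.fromstring(source)
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"malformed MEDLINE XML: {exc}") from exc
    else:
        try:
            root = etree.parse(str(source)).getroot()
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"malformed MEDLINE XML: {exc}") from exc

    records: list[ArticleRecord] = []
    skipped = 0
    for node in root.iter("PubmedArticle"):
        pmid = node.findtext(".//MedlineCitation/PMID")
        if not pmid:
            skipped += 1
            continue
        title = node.findtext(".//Article/ArticleTitle") or ""
        abstract = " ".join(
            (t.text or "") for t in node.findall(".//Abstract/AbstractText")
        ).strip()
        mesh = [
            d.text
            for d in node.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            if d.text
        ]
        pub_types = [
            p.text
            for p in node.findall(".//PublicationTypeList/PublicationType")
            if p.text
        ]
        journal = node.findtext(".//Article/Journal/Title") or ""
        year_text = node.findtext(".//Article/Journal/JournalIssue/PubDate/Year")
        year = int(year_text) if year_text and year_text.isdigit() else None
        records.append(
            ArticleRecord(pmid, title, abstract, mesh, pub_types, journal, year)
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} record(s) without a PMID", stacklevel=2)
    return records


def write_medline_xml(records: Sequence[ArticleRecord], path: Union[str, Path]) -> None:
    """Serialize records to eFetch-shaped XML (the fixture writer)."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.article_id
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        etree.SubElement(journal, "Title").text = rec.journal
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if rec.year is not None:
            etree.SubElement(pubdate, "Year").text = str(rec.year)
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = rec.abstract
        ptl = etree.SubElement(article, "PublicationTypeList")
        for pt in rec.publication_types:
            etree.SubElement(ptl, "PublicationType").text = pt
        mhl = etree.SubElement(cit, "MeshHeadingList")
        for term in rec.mesh_terms:
            mh = etree.SubElement(mhl, "MeshHeading")
            etree.SubElement(mh, "DescriptorName").text = term
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def data_features(
    rec: ArticleRecord,
    min_len: int = MIN_TOKEN_LEN,
    max_len: int = MAX_TOKEN_LEN,
) -> Counter:
    """Term-frequency map over the stemmed title + abstract tokens."""
    stops = stopwords()
    counts: Counter = Counter()
    for tok in tokenize(f"{rec.title} {rec.abstract}"):
        if tok in stops:
            continue
        stem = porter_stem(tok)
        if min_len <= len(stem) <= max_len:
            counts[stem] += 1
    return counts


def metadata_features(rec: ArticleRecord) -> Counter:
    """Term-frequency map over MeSH and publication-type tokens.

    Only tokenization and lowercasing are applied; tokens are prefixed so
    the metadata namespace never collides with data tokens.
    """
    counts: Counter = Counter()
    for label in list(rec.mesh_terms) + list(rec.publication_types):
        for tok in tokenize(label):
            counts[META_PREFIX + tok] += 1
    return counts


def combined_features(rec: ArticleRecord, use_metadata: bool = True) -> Counter:
    feats = data_features(rec)
    if use_metadata:
        feats.update(metadata_features(rec))
    return feats


@dataclass
class CorpusVectorizer:
    """Fitted corpus vectorizer: vocabulary + weighting, persisted with models."""

    pipeline: Pipeline
    scheme: str

    @property
    def vocabulary(self) -> list[str]:
        return list(self.pipeline.named_steps["dict"].get_feature_names_out())

    def transform(self, records: Sequence[ArticleRecord], use_metadata: bool = True):
        feats = [combined_features(r, use_metadata) for r in records]
        return self.pipeline.transform(feats)


def vectorize_corpus(
    records: Sequence[ArticleRecord],
    scheme: str = "tfidf",
    use_metadata: bool = True,
):
    """Build the sparse feature matrix over the union data+meta vocabulary.

    Returns ``(matrix, vectorizer)``; the vectorizer carries the vocabulary
    (sorted, hence deterministic) and the fitted IDF weights for reuse at
    prediction time.  Schemes: ``tfidf`` (default), ``count``, ``binary``.
    """
    if not records:
        raise ValueError("cannot vectorize an empty corpus")
    if scheme not in ("tfidf", "count", "binary"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    feats = [combined_features(r, use_metadata) for r in records]
    steps = [("dict", DictVectorizer(sort=True))]
    if scheme == "tfidf":
        steps.append(("weight", TfidfTransformer()))
    pipeline = Pipeline(steps)
    matrix = pipeline.fit_transform(feats)
    if scheme == "binary":
        matrix = (matrix > 0).astype(float)
    return matrix, CorpusVectorizer(pipeline, scheme)


# ---------------------------------------------------------------------------
# JSONL corpus I/O
# ---------------------------------------------------------------------------

def write_jsonl(
    records: Sequence[ArticleRecord],
    path: Union[str, Path],
    labels: Optional[Sequence[str]] = None,
) -> None:
    if labels is not None and len(labels) != len(records):
        raise ValueError("labels must align with records")
    with open(path, "w", encoding="utf-8") as fh:
        for i, rec in enumerate(records):
            row = asdict(rec)
            if labels is not None:
                row["label"] = labels[i]
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def read_jsonl(path: Union[str, Path]) -> tuple[list[ArticleRecord], Optional[list[str]]]:
    records: list[ArticleRecord] = []
    labels: list[str] = []
    any_label = False
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip():
            continue
        row = json.loads(line)
        label = row.pop("label", None)
        if label is not None:
            any_label = True
        labels.append(label)
        records.append(ArticleRecord(**row))
    return records, (labels if any_label else None)
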