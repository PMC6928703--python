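"""Deterministic test inputs: terminology, synthetic corpora, offline search.

The terminology fixture is a hand-authored SNOMED-CT/UMLS-style vocabulary
covering the worked hypertension scenario (female, blood pressure,
beta-blocker, ACE inhibitor, their drug-class parents) plus distractor
concepts from unrelated clinical areas.

The synthetic labeled corpus stands in for a licensed rigor/nonrigor gold
standard.  Each class draws abstract tokens from its own multinomial; the
KL separation between the two distributions and the probability of
trial-like metadata (a randomized-trial publication type, random-allocation
and follow-up MeSH terms) are controlled by the ``separation`` level, so
the rigor signal lives in both data and metadata features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from ._text import normalize
from .article_store import ArticleRecord
from .eqrm import LabeledCorpus, NONRIGOR, RIGOR
from .query_engine import BooleanQuery, SearchOutcome

__all__ = [
    "SCENARIO_TEXT",
    "CorpusSpec",
    "terminology_concepts",
    "make_terminology_fixture",
    "make_synthetic_corpus",
    "FixtureBackend",
    "make_fixture_backend",
]

#: Clinical scenario exercising the worked example end to end.
SCENARIO_TEXT = (
    "A 65 year old female presents with raised blood pressure readings. "
    "She currently takes a beta-blocker. Her doctor is considering an "
    "ACE inhibitor as an alternative."
)


def terminology_concepts() -> list[dict]:
    """The demo vocabulary, in fixture schema (deterministic, no RNG)."""
    drug = {"semantic_types": ["pharmacologic substance"], "entity_type": "chemical and drugs"}
    disorder = {"semantic_types": ["disease or syndrome"], "entity_type": "disorder"}
    finding = {"semantic_types": ["finding"], "entity_type": "finding"}
    procedure = {"semantic_types": ["diagnostic procedure"], "entity_type": "procedure"}
    concepts = [
        # --- scenario concepts -------------------------------------------
        {"id": "C0001", "name": "female",
         "synonyms": ["woman"], "semantic_types": ["population group"],
         "entity_type": "population", "parents": []},
        {"id": "C0002", "name": "blood pressure",
         "synonyms": ["arterial tension"], **finding, "parents": []},
        {"id": "C0003", "name": "beta-blocker",
         "synonyms": ["beta adrenergic blocking agent"], **drug,
         "parents": ["C0100"]},
        {"id": "C0004", "name": "angiotensin-converting-enzyme inhibitor",
         "synonyms": ["ACE inhibitor"], **drug, "parents": ["C0100"]},
        # --- class parents / translation anchors -------------------------
        {"id": "C0100", "name": "antihypertensive agent",
         "synonyms": [], **drug, "parents": []},
        {"id": "C0101", "name": "diagnostic procedure",
         "synonyms": [], **procedure, "parents": []},
        {"id": "C0102", "name": "risk factor",
         "synonyms": [], "semantic_types": ["qualitative concept"],
         "entity_type": "qualifier", "parents": []},
        {"id": "C0103", "name": "prognostic factor",
         "synonyms": [], "semantic_types": ["qualitative concept"],
         "entity_type": "qualifier", "parents": []},
        # --- distractors --------------------------------------------------
        {"id": "C0200", "name": "hypertension",
         "synonyms": ["hypertensive disorder"], **disorder, "parents": []},
        {"id": "C0201", "name": "type 2 diabetes mellitus",
         "synonyms": [], **disorder, "parents": []},
        {"id": "C0202", "name": "myocardial infarction",
         "synonyms": ["heart attack"], **disorder, "parents": []},
        {"id": "C0203", "name": "asthma", "synonyms": [], **disorder, "parents": []},
        {"id": "C0204", "name": "atrial fibrillation",
         "synonyms": [], **disorder, "parents": []},
        {"id": "C0205", "name": "stroke",
         "synonyms": ["cerebrovascular accident"], **disorder, "parents": []},
        {"id": "C0206", "name": "chronic kidney disease",
         "synonyms": [], **disorder, "parents": []},
        {"id": "C0207", "name": "osteoporosis", "synonyms": [], **disorder, "parents": []},
        {"id": "C0208", "name": "major depressive disorder",
         "synonyms": [], **disorder, "parents": []},
        {"id": "C0210", "name": "aspirin", "synonyms": [], **drug, "parents": ["C0211"]},
        {"id": "C0211", "name": "cardiovascular agent", "synonyms": [], **drug, "parents": []},
        {"id": "C0212", "name": "metformin", "synonyms": [], **drug, "parents": []},
        {"id": "C0213", "name": "atorvastatin", "synonyms": [], **drug, "parents": []},
        {"id": "C0214", "name": "warfarin", "synonyms": [], **drug, "parents": ["C0211"]},
        {"id": "C0215", "name": "amoxicillin", "synonyms": [], **drug, "parents": []},
        {"id": "C0216", "name": "albuterol", "synonyms": ["salbutamol"], **drug, "parents": []},
        {"id": "C0217", "name": "bisphosphonate", "synonyms": [], **drug, "parents": []},
        {"id": "C0220", "name": "electrocardiography",
         "synonyms": ["ecg"], **procedure, "parents": ["C0101"]},
        {"id": "C0221", "name": "colonoscopy", "synonyms": [], **procedure, "parents": ["C0101"]},
        {"id": "C0222", "name": "mammography", "synonyms": [], **procedure, "parents": ["C0101"]},
        {"id": "C0223", "name": "serum creatinine measurement",
         "synonyms": [], **procedure, "parents": ["C0101"]},
        {"id": "C0230", "name": "chest pain", "synonyms": [], **finding, "parents": []},
        {"id": "C0231", "name": "body mass index", "synonyms": ["bmi"], **finding, "parents": []},
        {"id": "C0232", "name": "smoking cessation",
         "synonyms": [], "semantic_types": ["therapeutic or preventive procedure"],
         "entity_type": "procedure", "parents": []},
        {"id": "C0233", "name": "influenza vaccination",
         "synonyms": ["flu shot"],
         "semantic_types": ["therapeutic or preventive procedure"],
         "entity_type": "procedure", "parents": []},
    ]
    return concepts


def make_terminology_fixture(path: Optional[Union[str, Path]] = None) -> str:
    """Serialize the demo vocabulary; byte-identical on every call."""
    payload = json.dumps(terminology_concepts(), indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(payload, encoding="utf-8")
    return payload


# ---------------------------------------------------------------------------
# Synthetic labeled corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    """Conditions of the synthetic rigor/nonrigor corpus."""

    n_articles: int = 2000
    rigor_fraction: float = 0.5
    separation: str = "high"
    vocab_size: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 20:
            raise ValueError("n_articles must be >= 20")
        if not (0 < self.rigor_fraction < 1):
            raise ValueError("rigor_fraction must be in (0, 1)")
        if self.separation not in ("high", "medium", "low"):
            raise ValueError(f"unknown separation {self.separation!r}")
        if self.vocab_size < 50:
            raise ValueError("vocab_size must be >= 50")


#: Class-conditional tilt of signal-token log-frequencies, per separation.
_TOKEN_DELTA = {"high": 2.5, "medium": 0.8, "low": 0.0}
#: P(trial-like metadata | rigor) / P(trial-like metadata | nonrigor).
_META_PROBS = {"high": (0.85, 0.10), "medium": (0.65, 0.35), "low": (0.5, 0.5)}

_GENERIC_MESH = (
    "Humans", "Female", "Male", "Adult", "Middle Aged", "Aged",
    "Treatment Outcome", "Risk Factors", "Prospective Studies",
)
_JOURNALS = (
    "Journal of Synthetic Medicine", "Annals of Generated Evidence",
    "Simulated Clinical Research", "Archives of Benchmark Trials",
)


def make_synthetic_corpus(spec: CorpusSpec) -> LabeledCorpus:
    """Generate a labeled corpus under the given conditions.

    Class balance matches ``rigor_fraction`` within one article; the whole
    corpus is a deterministic function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    V = spec.vocab_size
    vocab = np.array([f"term{i:04d}" for i in range(V)])

    base = rng.dirichlet(np.full(V, 0.6))
    n_signal = max(10, V // 8)
    signal = rng.choice(V, size=2 * n_signal, replace=False)
    rigor_sig, nonrigor_sig = signal[:n_signal], signal[n_signal:]
    delta = _TOKEN_DELTA[spec.separation]

    def tilt(up, down):
        logp = np.log(base)
        logp[up] += delta
        logp[down] -= delta
        p = np.exp(logp - logp.max())
        return p / p.sum()

    p_rigor = tilt(rigor_sig, nonrigor_sig)
    p_nonrigor = tilt(nonrigor_sig, rigor_sig)
    meta_rigor, meta_nonrigor = _META_PROBS[spec.separation]

    n_rigor = int(round(spec.n_articles * spec.rigor_fraction))
    labels = np.array([RIGOR] * n_rigor + [NONRIGOR] * (spec.n_articles - n_rigor))
    rng.shuffle(labels)

    records: list[ArticleRecord] = []
    for i, label in enumerate(labels):
        p = p_rigor if label == RIGOR else p_nonrigor
        title_tokens = rng.choice(vocab, size=8, p=p)
        n_abs = 40 + int(rng.poisson(40))
        abs_tokens = rng.choice(vocab, size=n_abs, p=p)
        sentences = []
        for start in range(0, n_abs, 12):
            chunk = abs_tokens[start : start + 12]
            if len(chunk):
                sentences.append(" ".join(chunk) + ".")
        trial_like = rng.random() < (meta_rigor if label == RIGOR else meta_nonrigor)
        pub_types = ["Randomized Controlled Trial" if trial_like else "Journal Article"]
        mesh = list(rng.choice(_GENERIC_MESH, size=3, replace=False))
        if trial_like:
            mesh += ["Random Allocation", "Follow-Up Studies"]
        records.append(
            ArticleRecord(
                article_id=f"SYN{i:06d}",
                title=" ".join(title_tokens).capitalize(),
                abstract=" ".join(sentences),
                mesh_terms=mesh,
                publication_types=pub_types,
                journal=str(rng.choice(_JOURNALS)),
                year=int(rng.integers(1995, 2025)),
            )
        )
    return LabeledCorpus(records, list(labels))


# ---------------------------------------------------------------------------
# Offline search backend
# ---------------------------------------------------------------------------

class FixtureBackend:
    """Deterministic in-memory search over a fixed article set.

    A term hits a record when its normalized form is a substring of the
    normalized title+abstract or of a normalized MeSH/publication-type
    label.  Groups OR their terms; the query ANDs its groups.
    """

    def __init__(self, records: Sequence[ArticleRecord]):
        self._records = {rec.article_id: rec for rec in records}
        self._text = {
            rec.article_id: normalize(f"{rec.title} {rec.abstract}")
            for rec in records
        }
        self._labels = {
            rec.article_id: [normalize(x) for x in rec.mesh_terms + rec.publication_types]
            for rec in records
        }

    def _term_hits(self, article_id: str, surface: str) -> bool:
        norm = normalize(surface)
        if norm and norm in self._text[article_id]:
            return True
        return any(norm in label for label in self._labels[article_id])

    def search(self, query: BooleanQuery) -> SearchOutcome:
        groups = [g for g in query.and_groups if g]
        if not groups:
            raise ValueError("cannot search an empty query")
        hits = [
            aid
            for aid in self._records
            if all(
                any(self._term_hits(aid, t.surface) for t in group)
                for group in groups
            )
        ]
        return SearchOutcome(tuple(hits), len(hits))

    def fetch(self, ids: Sequence[str]) -> list[ArticleRecord]:
        return [self._records[i] for i in ids if i in self._records]


def make_fixture_backend(records: Sequence[ArticleRecord]) -> FixtureBackend:
    return FixtureBackend(records)
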