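# litcurate

Automated curation of biomedical literature for evidence-based practice:
build a well-built clinical question from whatever a health system already
has (free-text scenarios, structured records, CDSS knowledge rules), turn
it into a PubMed boolean query, classify the retrieved articles for
methodological rigor, and grade, rank and summarize what survives.

## The problem

Clinicians, researchers and patients all reach for external research
evidence, but assembling it is manual: someone has to phrase the question,
fight with the search box, and read past the methodologically weak papers.
`litcurate` automates that loop end to end:

1. **Question construction.** Input text is tokenized, stopword-filtered
   and Porter-stemmed; candidate n-grams are matched against a
   SNOMED-CT/UMLS-style vocabulary by *salient term identification* (STI),
   a weighted matcher in which an exact hit on a preferred name scores
   `w = 1.0` and synonym or partial hits score `w = 0.5`. Matched concepts
   are slotted into **PICO** (Patient/problem, Intervention, Comparison,
   Outcome) by their semantic and entity types — a *population group*
   concept goes to P, a *chemical and drugs* concept to I (the second such
   concept to C). Knowledge rules map directly: the rule's data elements
   → P, its actions → I and C, its purpose → O. The query purpose
   (treatment / diagnosis / prognosis / etiology) is inferred by majority
   vote over the translated parents of the I∪C concepts.
2. **Query optimization.** The question renders as
   `P₁ AND P₂ AND (I OR C) AND O`. If too few results come back, terms are
   dropped one at a time — C first, then O, then the lowest-STI-weight term
   of the P∪I core — until a result threshold is met or one term remains.
3. **Rigor classification (E-QRM).** A two-level ensemble over TF-IDF data
   features (stemmed title+abstract tokens) and metadata features (MeSH and
   publication-type tokens, unstemmed, in a disjoint namespace): level 1
   wraps gradient boosted trees in SAMME AdaBoost; level 2 soft-votes
   AdaBoost(GBT) with an L2 logistic GLM. The target is binary:
   `rigor` vs `nonrigor`.
4. **Ranking and summarization.** Articles are graded H > M > L > U from a
   publication-type ranking table (systematic reviews rank 1/H … any other
   type 11/L), crossed with user-context grades by per-column majority vote
   (ties to the higher grade) and a final maximum. Primary studies get an
   extractive P/I/O summary from their abstract sentences (a comparator is
   itself an intervention, so C folds into I); secondary studies
   (systematic reviews, meta-analyses) keep their metadata only. Summaries
   cluster into evidence groups by single-linkage Jaccard similarity.

Since the licensed gold-standard rigor corpus cannot ship, the package
includes a synthetic corpus generator with controllable class separation in
both token and metadata space; see `docs/methods.md` for what that does and
does not demonstrate.

## Worked example

```bash
litcurate make-fixtures --out fx --n 200 --seed 1
litcurate train --corpus fx/corpus.jsonl --out model.joblib --seed 1
litcurate build-query \
  --text "A 65 year old female presents with raised blood pressure readings. \
She currently takes a beta-blocker. Her doctor is considering an ACE \
inhibitor as an alternative." \
  --terminology fx/terminology.json
```

The train step prints its held-out evaluation on the synthetic corpus:

```
held-out: accuracy=1.000 precision=1.000 F=1.000 AUC=1.000 (n=60)
```

(the default generator is strongly separated, so a 200-article corpus is
learned perfectly), and `build-query` prints the slotted question and query:

```json
{
  "pico": {
    "P": [{"surface": "female", "concept_id": "C0001", "weight": 1.0},
          {"surface": "blood pressure", "concept_id": "C0002", "weight": 1.0}],
    "I": [{"surface": "beta-blocker", "concept_id": "C0003", "weight": 1.0}],
    "C": [{"surface": "ACE inhibitor", "concept_id": "C0004", "weight": 0.5}],
    "O": [],
    "query_type": "treatment"
  },
  "query": "female AND blood pressure AND (beta-blocker OR ACE inhibitor)"
}
```

`female` and `blood pressure` matched exactly (w = 1.0); `ACE inhibitor`
matched as a synonym of *angiotensin-converting-enzyme inhibitor*
(w = 0.5) and, being the second drug concept, became the comparator. Both
drugs' parent concept (*antihypertensive agent*) translates to
*treatment*, which becomes the PubMed clinical-queries filter in the
`pubmed` rendering. `litcurate run` chains search, classification,
ranking and summarization into a single JSON report; `classify`, `rank`
and `summarize` run the stages standalone.

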