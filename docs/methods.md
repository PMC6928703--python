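# Methods

This note documents the models and procedures `litcurate` implements, the
parameters that matter, the synthetic data used in testing, and the design
choices made where the design was genuinely open.

## Concept matching (STI)

Matching is surface-level against a controlled vocabulary. Names and input
terms are normalized identically — lowercase, punctuation replaced by
whitespace, whitespace collapsed — and never stemmed: vocabulary entries
are surface forms, and stemming "angiotensin-converting-enzyme" would
break them. Match levels and weights:

| level   | condition                                               | weight |
|---------|---------------------------------------------------------|--------|
| exact   | normalized term equals a preferred name                 | 1.0    |
| synonym | normalized term equals a listed synonym                 | 0.5    |
| partial | term token set a proper subset of a name's (or vice versa) with ≥1 shared token of ≥4 characters | 0.5 |

Precedence is exact > synonym > partial: a synonym is a whole-name match
and therefore more trustworthy than a fragment. Ties within a level go to
the longest matched name, then the lexicographically smallest concept id,
so matching is a pure function of the store. One deliberate asymmetry:
when *scanning running text* (question construction, sentence scoring) the
partial rule is restricted to the term-is-fragment direction
(`partial_mode="fragment"`). An arbitrary 4-token window that merely
*contains* "female" is not a mention of a longer name, and accepting the
superset direction there would let window artifacts outrank exact
single-token matches. Standalone lookups keep both directions.

Stemming still participates in question construction: the stemmed form of
each matched phrase is recorded so that repeated surface variants of one
phrase are slotted only once.

## PICO construction

Free text: whitespace tokenization → English stopword removal (packaged
list, 174 entries) → greedy longest-first n-gram matching (n ≤ 4). Each
matched concept is slotted once via the semantic-type/entity-type mapping
table (`data/slot_mapping.json`): population/disorder/finding types → P,
drug/procedure types → intervention class, outcome/qualifier types → O.
The first intervention-class concept becomes I and every later one C,
which reads the comparative question the way PICO intends and reproduces
the OR-grouping of two drugs in the worked scenario. Types missing from
the table fall back to P with a warning — a matched concept is never
dropped silently. The mapping table is a reconstruction: only two
anchor examples exist (population group → P, chemical and drugs → I), so
the remaining rows are editable config, not code.

Knowledge rules map data elements → P, first action → I, later actions →
C, purpose → O; production rules commonly lack a purpose and leave O
empty. Structured records with pre-labeled slots pass through, with STI
used only to attach concept ids and weights.

Query purpose: parents of the I∪C concepts are translated
(`data/query_type_translation.json`) and majority-voted; ties resolve by
the fixed priority treatment > diagnosis > prognosis > etiology, and no
votes yields `unknown`. `unknown` suppresses the clinical filter rather
than guessing.

## Query building and relaxation

Rendering: each P term is its own AND-group, I and C terms form a single
OR-group, O terms trail as AND-groups. The `pubmed` dialect appends the
clinical-queries filter clause for the inferred purpose (broad-scope
filter strings live in `data/clinical_filters.json`).

Relaxation: search; while the hit count is below `min_results` (default 1),
drop exactly one term — any C term first, then any O term, then the
lowest-weight P∪I term; within a slot, ties go to the lowest weight and
then the most recently added term — and stop at the threshold or when one
term remains. A still-empty single-term outcome is returned for the caller
to flag rather than raised. The "too many results" branch is deliberately
just a warning (`max_results`): re-adding terms has no defined order and
is better left to the user. The loop performs at most (terms − 1)
removals, and no core term is ever dropped while a C or O term remains.

## Features and the rigor classifier

Data features: title+abstract tokens, lowercased, stopword-filtered,
Porter-stemmed (a full implementation of the 1980 algorithm, property- and
vocabulary-tested), length-filtered to 2–25 characters. Metadata features:
MeSH and publication-type tokens, lowercased only — controlled labels need
neither stopword removal nor stemming — and prefixed (`meta::`) so the two
namespaces stay disjoint. Default weighting is TF-IDF over the union
vocabulary (sorted, hence deterministic); `count` and `binary` schemes are
selectable for ablation.

E-QRM: the level-2 combiner soft-votes the rigor probabilities of
AdaBoost(gradient boosted trees) and an L2-penalized logistic GLM,
threshold 0.5; a logistic stacking meta-learner is an optional mode.
"Deep learning" is a feed-forward MLP (two hidden layers, 32/16 by
default) — no claim is made beyond a multilayer network. The plain
`logistic_regression` learner is kept distinct from the GLM (effectively
unpenalized vs ridge). AdaBoost is a SAMME booster (default 50 rounds)
that reweights when the base accepts `sample_weight` and otherwise fits a
weighted bootstrap resample; it stops early at zero weighted error (the
base already fits the sample, so one model carries all the weight) or at
error ≥ 0.5. All estimators derive their random state from the single
ensemble seed, making train+evaluate bit-stable on one machine.

Evaluation takes `rigor` as the positive class (configurable): precision,
F (= 2PR/(P+R), held exactly), accuracy (= (TP+TN)/n, held exactly) and
AUC as the rank statistic over predicted probabilities, reported absent
when the test set has a single class. Splits are stratified at a default
train ratio of 0.7.

## Grading and ranking

The publication-type table (`data/pubtype_ranks.json`) ranks types 1–11
with grades banded H (rank ≤ 3), M (4–7), L (≥ 8); the loader enforces the
band invariant. Articles with several types take their best (minimum)
rank; unlisted and missing types fall to the "any other" row (11, L).
Common MEDLINE names are aliased onto the table rows (e.g. "Meta-Analysis"
→ the meta-analysis-of-RCTs row, "Case Reports" → the cohort/case row).

Cross-context grading: user-context rows × evidence-property columns of
H/M/L/U cells; each column aggregates by majority vote with ties broken
toward the higher grade, and the final grade is the maximum aggregate.
One caveat discovered by property testing: majority voting is **not
monotone in single cells** — raising one cell can hand a lower grade a
strict majority it previously only tied — so the monotonicity this module
guarantees is over columns (adding a column never lowers the final grade),
not cells. Mapping raw user profiles to grades is out of scope; context
arrives pre-graded.

The presentation sort key is (cross-context grade desc, publication-type
rank asc, rigor probability desc, year desc), stable on full ties.

## Summarization

Secondary studies (any publication type containing "systematic review" or
"meta-analysis") are stored as evidence with metadata only — they already
synthesize primary work. For primary studies the abstract is split by a
rule-based splitter (terminal punctuation plus an abbreviation guard), and
each sentence is scored per element by the summed STI weights of the
concepts it mentions; C-class concepts score as I. A sentence joins every
element whose score exceeds the threshold (default 0), with at most k
(default 3) sentences per element kept in document order — every summary
sentence is verbatim from the source. Whole-article summaries concatenate
P, I, O. Evidence grouping is single-linkage over Jaccard similarity of
summary token sets (default threshold 0.5): a partition, order-stable,
with transitive chaining accepted as the price of single linkage. Since no
quantitative benchmark exists for this stage, its tests are structural
(verbatim extraction, partition, linkage behavior) rather than quality
scores.

## Synthetic corpus

The generator stands in for a licensed, manually annotated rigor corpus.
Per class, abstract and title tokens are drawn from a multinomial over a
synthetic vocabulary (default 300 types); a signal subset (vocab/8 tokens
per class) has its log-frequency tilted by ±δ with δ = 2.5 / 0.8 / 0.0 for
separation high / medium / low. Rigor articles additionally receive
trial-like metadata — a randomized-trial publication type plus
random-allocation and follow-up MeSH terms — with probability 0.85 / 0.65
/ 0.50 against 0.10 / 0.35 / 0.50 for nonrigor, so the class signal lives
in both feature blocks and data-only vs data+meta ablations are
meaningful. Class balance matches `rigor_fraction` (default 0.5) within
one article; everything is a deterministic function of the spec.

What passing tests show: the pipeline recovers a strong, known signal
(high separation ⇒ ensemble accuracy ≥ 0.95 at n = 2000) and degrades to
chance when there is none (low separation; permuted labels). What they do
not show: performance on real abstracts, whose signal is far subtler and
whose vocabulary is nonstationary. One measured subtlety: on a separable
corpus, a classifier trained on *permuted* labels amplifies the chance
agreement between the permutation and the truth, so single-permutation
accuracies scatter several points around 0.5 with random sign; the chance
check therefore either averages permutations (unit test) or runs at the
fixed benchmark conditions (n = 2000, seed 7).

## Problem sizes and numerical choices

Unit tests run at n = 120–600 articles with reduced vocabularies and
boosting rounds; the benchmark recovery block runs at its stated
conditions (separation high, n = 2000, split 0.7, seed 7). Reports
serialize with sorted keys and rounded probabilities (6 decimals) so
repeated runs are byte-identical. Terminology tie-breaks, vote
tie-breaks and removal order are all total, so every pipeline stage is
deterministic given its inputs and seed.

## Known limitations

* Full Arden-syntax MLM parsing, sensor-context recognition and full-text
  PDF extraction are out of scope; rules arrive pre-extracted and
  summarization runs on abstracts.
* The semantic-type → PICO table and the query-type translation table are
  reconstructions anchored on a handful of examples; both ship as editable
  JSON.
* The live PubMed backend (Entrez ePost/eSearch/eFetch with history) is
  thin and untested offline; the fixture backend is the tested contract.
* Evidence grouping by Jaccard single linkage is intentionally simple;
  near-duplicate abstracts group well, paraphrases may not.
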