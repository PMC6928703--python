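"""Two-level ensemble classifier for methodological rigor (E-QRM).

The target is binary — ``rigor`` (methodologically sound) vs ``nonrigor``.
Level 0 is a pool of individual learners (naive Bayes, decision tree,
logistic regression, GLM, random forest, gradient boosted trees and a
feed-forward network standing in for "deep learning").  Level 1 wraps the
strongest individual learners in AdaBoost.  Level 2 combines AdaBoost(GBT)
and the GLM by soft voting (a logistic stacking meta-learner is an
optional mode).

AdaBoost is a SAMME booster that reweights the training sample each round;
bases that do not accept sample weights (the network) are fitted on a
weighted bootstrap resample instead.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .article_store import ArticleRecord, CorpusVectorizer, vectorize_corpus

__all__ = [
    "RIGOR",
    "NONRIGOR",
    "LabeledCorpus",
    "EnsembleSpec",
    "EvalReport",
    "split_corpus",
    "train_base",
    "train_adaboost",
    "train_eqrm",
    "evaluate",
    "SammeAdaBoost",
    "EqrmModel",
    "train_bundle",
    "save_bundle",
    "load_bundle",
    "ModelBundle",
]

RIGOR = "rigor"
NONRIGOR = "nonrigor"

BASE_LEARNERS = (
    "naive_bayes",
    "decision_tree",
    "logistic_regression",
    "glm",
    "random_forest",
    "gradient_boosted_trees",
    "deep_mlp",
)

#: Default hyperparameters per base learner; overridable per call.
DEFAULT_PARAMS: dict[str, dict] = {
    "naive_bayes": {},
    "decision_tree": {"max_depth": 8},
    # plain logistic regression is effectively unpenalized (huge C); the GLM
    # keeps the default L2 (binomial ridge), mirroring the two listed learners
    "logistic_regression": {"C": 1e6, "max_iter": 2000},
    "glm": {"C": 1.0, "max_iter": 2000},
    "random_forest": {"n_estimators": 200},
    "gradient_boosted_trees": {"n_estimators": 80, "max_depth": 3},
    "deep_mlp": {"hidden_layer_sizes": (32, 16), "max_iter": 300},
}

DEFAULT_ADABOOST_ROUNDS = 50


class ConfigurationError(ValueError):
    """Invalid learner kind or ensemble specification."""


@dataclass
class LabeledCorpus:
    records: list[ArticleRecord]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels must align")
        bad = set(self.labels) - {RIGOR, NONRIGOR}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EnsembleSpec:
    """Architecture of the two-level ensemble."""

    base_learners: tuple[str, ...] = ("gradient_boosted_trees", "glm")
    boosted: tuple[str, ...] = ("gradient_boosted_trees",)
    stack_members: tuple[str, ...] = ("adaboost:gradient_boosted_trees", "glm")
    split_ratio: float = 0.7
    adaboost_rounds: int = DEFAULT_ADABOOST_ROUNDS
    combiner: str = "soft_vote"  # or "stacking"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split_ratio < 1):
            raise ConfigurationError("split_ratio must be in (0, 1)")
        if len(self.stack_members) < 2:
            raise ConfigurationError("the level-2 ensemble needs >= 2 members")
        if self.combiner not in ("soft_vote", "stacking"):
            raise ConfigurationError(f"unknown combiner {self.combiner!r}")


@dataclass
class EvalReport:
    """Held-out evaluation metrics; positive class is ``rigor``."""

    f_measure: float
    precision: float
    accuracy: float
    auc: Optional[float]
    confusion: tuple[tuple[int, int], tuple[int, int]]  # [[TN, FP], [FN, TP]]
    n_test: int


def split_corpus(
    corpus: LabeledCorpus, ratio: float = 0.7, seed: int = 0
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Stratified train/test split (train fraction = ``ratio``)."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    counts = {lbl: corpus.labels.count(lbl) for lbl in set(corpus.labels)}
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("both classes must be present with >= 2 members")
    idx = np.arange(len(corpus))
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=corpus.labels, random_state=seed
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    pick = lambda ix: LabeledCorpus(
        [corpus.records[i] for i in ix], [corpus.labels[i] for i in ix]
    )
    return pick(train_idx), pick(test_idx)


def _make_estimator(kind: str, seed: int, params: Optional[dict] = None):
    if kind not in BASE_LEARNERS:
        raise ConfigurationError(f"unsupported learner kind {kind!r}")
    kw = dict(DEFAULT_PARAMS[kind])
    if params:
        kw.update(params)
    if kind == "naive_bayes":
        return MultinomialNB(**kw)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **kw)
    if kind in ("logistic_regression", "glm"):
        return LogisticRegression(random_state=seed, **kw)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **kw)
    if kind == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=seed, **kw)
    return MLPClassifier(random_state=seed, **kw)


def train_base(kind: str, X, y: Sequence[str], seed: int = 0, **params):
    """Fit one probabilistic base learner."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("cannot train on an empty set")
    est = _make_estimator(kind, seed, params)
    est.fit(X, y)
    return est


class SammeAdaBoost(BaseEstimator, ClassifierMixin):
    """Discrete (SAMME) AdaBoost over an arbitrary probabilistic base.

    Bases exposing ``sample_weight`` are reweighted directly; others are
    fitted on a weighted bootstrap resample.  Boosting stops early when a
    round's weighted error reaches zero (the base already fits the sample)
    or 0.5 (no better than chance on the reweighted sample).
    """

    def __init__(self, base_estimator, n_rounds: int = 50, random_state: int = 0):
        self.base_estimator = base_estimator
        self.n_rounds = n_rounds
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_rounds < 1:
            raise ConfigurationError("n_rounds must be >= 1")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("SAMME booster is binary here")
        n = y.shape[0]
        rng = np.random.default_rng(self.random_state)
        supports_weight = "sample_weight" in inspect.signature(
            self.base_estimator.fit
        ).parameters
        w = np.full(n, 1.0 / n)
        self.estimators_: list = []
        self.alphas_: list[float] = []
        for m in range(self.n_rounds):
            est = clone(self.base_estimator)
            if hasattr(est, "random_state"):
                est.set_params(random_state=self.random_state + m)
            if supports_weight:
                est.fit(X, y, sample_weight=w)
            else:
                idx = rng.choice(n, size=n, replace=True, p=w)
                Xi = X[idx] if not sparse.issparse(X) else X[idx]
                est.fit(Xi, y[idx])
            pred = est.predict(X)
            err = float(w[pred != y].sum())
            if err <= 1e-12:
                self.estimators_ = [est]
                self.alphas_ = [1.0]
                break
            if err >= 0.5:
                if not self.estimators_:
                    self.estimators_ = [est]
                    self.alphas_ = [1.0]
                break
            alpha = float(np.log((1.0 - err) / err))
            self.estimators_.append(est)
            self.alphas_.append(alpha)
            w = w * np.exp(alpha * (pred != y))
            w /= w.sum()
        return self

    def predict_proba(self, X):
        alphas = np.asarray(self.alphas_)
        probs = np.zeros((X.shape[0], len(self.classes_)))
        for a, est in zip(alphas, self.estimators_):
            p = est.predict_proba(X)
            cols = [list(est.classes_).index(c) for c in self.classes_]
            probs += a * p[:, cols]
        return probs / alphas.sum()

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_adaboost(
    base_kind: str,
    X,
    y: Sequence[str],
    rounds: int = DEFAULT_ADABOOST_ROUNDS,
    seed: int = 0,
    **params,
):
    """Boost one base learner kind for ``rounds`` rounds."""
    if rounds < 1:
        raise ConfigurationError("rounds must be >= 1")
    base = _make_estimator(base_kind, seed, params)
    booster = SammeAdaBoost(base, n_rounds=rounds, random_state=seed)
    booster.fit(X, np.asarray(y))
    return booster


class EqrmModel:
    """Level-2 combiner over named member models."""

    def __init__(self, members: dict[str, object], combiner: str = "soft_vote",
                 meta=None):
        if len(members) < 2:
            raise ConfigurationError("E-QRM needs >= 2 stack members")
        self.members = members
        self.combiner = combiner
        self.meta = meta
        first = next(iter(members.values()))
        self.classes_ = np.asarray(first.classes_)

    def member_probabilities(self, X) -> dict[str, np.ndarray]:
        """Per-member P(rigor) — the member attribution view."""
        out = {}
        for name, est in self.members.items():
            p = est.predict_proba(X)
            col = list(est.classes_).index(RIGOR)
            out[name] = p[:, col]
        return out

    def predict_proba(self, X):
        stacked = np.column_stack(list(self.member_probabilities(X).values()))
        if self.combiner == "stacking" and self.meta is not None:
            p_rigor = self.meta.predict_proba(stacked)[
                :, list(self.meta.classes_).index(RIGOR)
            ]
        else:
            p_rigor = stacked.mean(axis=1)
        probs = np.zeros((X.shape[0], 2))
        rigor_col = list(self.classes_).index(RIGOR)
        probs[:, rigor_col] = p_rigor
        probs[:, 1 - rigor_col] = 1.0 - p_rigor
        return probs

    def predict(self, X):
        p = self.predict_proba(X)
        rigor_col = list(self.classes_).index(RIGOR)
        return np.where(p[:, rigor_col] >= 0.5, RIGOR, NONRIGOR)


def _train_member(name: str, X, y, spec: EnsembleSpec):
    if name.startswith("adaboost:"):
        kind = name.split(":", 1)[1]
        return train_adaboost(kind, X, y, rounds=spec.adaboost_rounds, seed=spec.seed)
    return train_base(name, X, y, seed=spec.seed)


def train_eqrm(X, y: Sequence[str], spec: Optional[EnsembleSpec] = None) -> EqrmModel:
    """Train the two-level ensemble on featurized training data."""
    spec = spec or EnsembleSpec()
    y = np.asarray(y)
    members = {name: _train_member(name, X, y, spec) for name in spec.stack_members}
    meta = None
    if spec.combiner == "stacking":
        stacked = np.column_stack(
            [
                est.predict_proba(X)[:, list(est.classes_).index(RIGOR)]
                for est in members.values()
            ]
        )
        meta = LogisticRegression(max_iter=2000, random_state=spec.seed)
        meta.fit(stacked, y)
    return EqrmModel(members, spec.combiner, meta)


def evaluate(model, X, y: Sequence[str]) -> EvalReport:
    """Score a fitted model on held-out data.

    F-measure and precision take ``rigor`` as the positive class; AUC is
    the rank statistic over the predicted rigor probabilities and is
    reported absent when the test set has a single class.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("test set must be non-empty")
    pred = np.asarray(model.predict(X))
    tp = int(np.sum((pred == RIGOR) & (y == RIGOR)))
    fp = int(np.sum((pred == RIGOR) & (y == NONRIGOR)))
    fn = int(np.sum((pred == NONRIGOR) & (y == RIGOR)))
    tn = int(np.sum((pred == NONRIGOR) & (y == NONRIGOR)))
    n = int(y.size)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / n
    auc: Optional[float] = None
    if len(np.unique(y)) == 2:
        proba = model.predict_proba(X)
        col = list(model.classes_).index(RIGOR)
        auc = float(roc_auc_score((y == RIGOR).astype(int), proba[:, col]))
    return EvalReport(f, precision, accuracy, auc, ((tn, fp), (fn, tp)), n)


# ---------------------------------------------------------------------------
# Bundled training over a labeled corpus
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything needed to classify new articles: model + vocabulary + spec."""

    model: EqrmModel
    vectorizer: CorpusVectorizer
    spec: EnsembleSpec
    report: EvalReport

    def score_records(self, records: Sequence[ArticleRecord]) -> np.ndarray:
        """P(rigor) for each record."""
        X = self.vectorizer.transform(records)
        col = list(self.model.classes_).index(RIGOR)
        return self.model.predict_proba(X)[:, col]


def train_bundle(
    corpus: LabeledCorpus,
    spec: Optional[EnsembleSpec] = None,
    scheme: str = "tfidf",
) -> ModelBundle:
    """Split, featurize, train and evaluate in one step."""
    spec = spec or EnsembleSpec()
    train, test = split_corpus(corpus, spec.split_ratio, spec.seed)
    _, vectorizer = vectorize_corpus(train.records, scheme=scheme)
    X_train = vectorizer.transform(train.records)
    X_test = vectorizer.transform(test.records)
    model = train_eqrm(X_train, train.labels, spec)
    report = evaluate(model, X_test, test.labels)
    return ModelBundle(model, vectorizer, spec, report)


def save_bundle(bundle: ModelBundle, path) -> None:
    joblib.dump(bundle, path)


def load_bundle(path) -> ModelBundle:
    return joblib.load(path)
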