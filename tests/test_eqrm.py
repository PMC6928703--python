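"""Splitting, base learners, metrics and the two-level ensemble mechanics."""

import numpy as np
import pytest

from litcurate.article_store import ArticleRecord, vectorize_corpus
from litcurate.eqrm import (
    ConfigurationError,
    EnsembleSpec,
    EqrmModel,
    LabeledCorpus,
    NONRIGOR,
    RIGOR,
    evaluate,
    load_bundle,
    save_bundle,
    split_corpus,
    train_adaboost,
    train_base,
    train_bundle,
    train_eqrm,
)
from litcurate.fixtures import CorpusSpec, make_synthetic_corpus


def _corpus(n_rigor, n_nonrigor):
    records = [ArticleRecord(str(i), title=f"doc {i}") for i in range(n_rigor + n_nonrigor)]
    labels = [RIGOR] * n_rigor + [NONRIGOR] * n_nonrigor
    return LabeledCorpus(records, labels)


class TestSplit:
    def test_stratified_counts_within_one(self):
        train, test = split_corpus(_corpus(60, 40), 0.7, seed=0)
        assert len(train) == 70 and len(test) == 30
        assert abs(train.labels.count(RIGOR) - 42) <= 1
        assert abs(train.labels.count(NONRIGOR) - 28) <= 1

    def test_default_ratio_is_point_seven(self):
        assert EnsembleSpec().split_ratio == 0.7

    def test_same_seed_gives_identical_partition(self):
        c = _corpus(30, 30)
        a = split_corpus(c, 0.7, seed=5)
        b = split_corpus(c, 0.7, seed=5)
        assert [r.article_id for r in a[0].records] == [
            r.article_id for r in b[0].records
        ]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_corpus(_corpus(50, 0), 0.7, seed=0)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_corpus(_corpus(10, 10), 1.2, seed=0)


class TestBaseLearners:
    def test_separable_toy_problem_fits_exactly(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = [NONRIGOR, NONRIGOR, RIGOR, RIGOR]
        model = train_base("gradient_boosted_trees", X, y, seed=0)
        assert list(model.predict(X)) == y

    def test_glm_beats_no_information_rate(self, small_split):
        X, y, Xte, yte = small_split
        model = train_base("glm", X, y, seed=13)
        rep = evaluate(model, Xte, yte)
        baseline = max(yte.count(RIGOR), yte.count(NONRIGOR)) / len(yte)
        assert rep.accuracy > baseline

    def test_unsupported_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            train_base("quantum_forest", np.zeros((2, 1)), [RIGOR, NONRIGOR])

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_base("deep_mlp", np.zeros((0, 3)), [])


class TestAdaBoost:
    def test_one_round_behaves_as_single_base(self, small_split):
        X, y, Xte, _ = small_split
        boosted = train_adaboost("decision_tree", X, y, rounds=1, seed=13)
        plain = train_base("decision_tree", X, y, seed=13)
        assert (boosted.predict(Xte) == plain.predict(Xte)).all()

    def test_matches_sklearn_adaboost_on_toy_problem(self):
        """Cross-check the SAMME booster against sklearn's implementation."""
        from sklearn.datasets import make_classification
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        X, yb = make_classification(
            n_samples=120, n_features=6, n_informative=3, random_state=3
        )
        y = np.where(yb == 1, RIGOR, NONRIGOR)
        ours = train_adaboost("decision_tree", X, y, rounds=20, seed=0, max_depth=1)
        ref = AdaBoostClassifier(
            DecisionTreeClassifier(max_depth=1, random_state=0),
            n_estimators=20,
            random_state=0,
        ).fit(X, y)
        agreement = float(np.mean(ours.predict(X) == ref.predict(X)))
        assert agreement >= 0.95

    def test_invalid_rounds_rejected(self):
        with pytest.raises(ConfigurationError):
            train_adaboost("decision_tree", np.zeros((2, 1)),
                           [RIGOR, NONRIGOR], rounds=0)


class TestEnsemble:
    def test_consensus_members_reproduce_common_prediction(self):
        class Stub:
            classes_ = np.array([NONRIGOR, RIGOR])

            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.tile([1 - self.p, self.p], (X.shape[0], 1))

        model = EqrmModel({"a": Stub(0.9), "b": Stub(0.8)})
        X = np.zeros((4, 2))
        assert list(model.predict(X)) == [RIGOR] * 4
        model_neg = EqrmModel({"a": Stub(0.1), "b": Stub(0.2)})
        assert list(model_neg.predict(X)) == [NONRIGOR] * 4

    def test_single_member_rejected(self):
        with pytest.raises(ConfigurationError):
            EqrmModel({"only": object()})
        with pytest.raises(ConfigurationError):
            EnsembleSpec(stack_members=("glm",))

    def test_ensemble_not_below_members_minus_tolerance(self, small_split):
        X, y, Xte, yte = small_split
        spec = EnsembleSpec(seed=13, adaboost_rounds=5)
        model = train_eqrm(X, y, spec)
        ens_acc = evaluate(model, Xte, yte).accuracy
        for name, member in model.members.items():
            member_acc = evaluate(member, Xte, yte).accuracy
            assert ens_acc >= member_acc - 0.02, name

    def test_stacking_combiner_mode(self, small_split):
        X, y, Xte, yte = small_split
        spec = EnsembleSpec(seed=13, adaboost_rounds=3, combiner="stacking")
        model = train_eqrm(X, y, spec)
        assert evaluate(model, Xte, yte).accuracy > 0.8

    def test_member_attributions_exposed(self, small_split):
        X, y, Xte, _ = small_split
        model = train_eqrm(X, y, EnsembleSpec(seed=13, adaboost_rounds=3))
        attrib = model.member_probabilities(Xte[:5])
        assert set(attrib) == {"adaboost:gradient_boosted_trees", "glm"}
        for probs in attrib.values():
            assert probs.shape == (5,)
            assert ((0 <= probs) & (probs <= 1)).all()


class _ConstantModel:
    classes_ = np.array([NONRIGOR, RIGOR])

    def predict(self, X):
        return np.array([RIGOR] * X.shape[0])

    def predict_proba(self, X):
        return np.tile([0.5, 0.5], (X.shape[0], 1))


class TestEvaluate:
    def test_perfect_classifier_scores_one(self):
        class Perfect:
            classes_ = np.array([NONRIGOR, RIGOR])

            def __init__(self, y):
                self.y = np.asarray(y)

            def predict(self, X):
                return self.y

            def predict_proba(self, X):
                p = (self.y == RIGOR).astype(float)
                return np.column_stack([1 - p, p])

        y = [RIGOR, NONRIGOR, RIGOR, NONRIGOR]
        rep = evaluate(Perfect(y), np.zeros((4, 1)), y)
        assert (rep.f_measure, rep.precision, rep.accuracy, rep.auc) == (1, 1, 1, 1)
        (tn, fp), (fn, tp) = rep.confusion
        assert fp == fn == 0 and tp == 2 and tn == 2

    def test_constant_classifier_is_chance_level(self):
        y = [RIGOR] * 10 + [NONRIGOR] * 10
        rep = evaluate(_ConstantModel(), np.zeros((20, 1)), y)
        assert rep.accuracy == 0.5
        assert rep.auc == 0.5

    def test_closed_form_confusion_metrics(self):
        class Fixed:
            classes_ = np.array([NONRIGOR, RIGOR])

            def __init__(self, pred):
                self.pred = np.asarray(pred)

            def predict(self, X):
                return self.pred

            def predict_proba(self, X):
                p = (self.pred == RIGOR).astype(float)
                return np.column_stack([1 - p, p])

        # TP=8, FP=2, FN=2, TN=8
        y = [RIGOR] * 10 + [NONRIGOR] * 10
        pred = [RIGOR] * 8 + [NONRIGOR] * 2 + [RIGOR] * 2 + [NONRIGOR] * 8
        rep = evaluate(Fixed(pred), np.zeros((20, 1)), y)
        assert rep.precision == pytest.approx(0.8)
        assert rep.f_measure == pytest.approx(0.8)
        assert rep.confusion == ((8, 2), (2, 8))

    def test_metric_identities_hold_exactly(self, small_split):
        X, y, Xte, yte = small_split
        model = train_base("glm", X, y, seed=13)
        rep = evaluate(model, Xte, yte)
        (tn, fp), (fn, tp) = rep.confusion
        assert rep.accuracy == (tp + tn) / rep.n_test
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        expected_f = 2 * p * r / (p + r) if p + r else 0.0
        assert rep.f_measure == expected_f

    def test_one_class_test_set_has_absent_auc(self):
        y = [RIGOR] * 5
        rep = evaluate(_ConstantModel(), np.zeros((5, 1)), y)
        assert rep.auc is None
        assert rep.accuracy == 1.0

    def test_auc_equals_pairwise_rank_statistic(self, small_split):
        """AUC cross-checked against brute-force pair counting."""
        X, y, Xte, yte = small_split
        model = train_base("naive_bayes", X, y, seed=13)
        rep = evaluate(model, Xte, yte)
        col = list(model.classes_).index(RIGOR)
        scores = model.predict_proba(Xte)[:, col]
        yarr = np.asarray(yte)
        pos = scores[yarr == RIGOR]
        neg = scores[yarr == NONRIGOR]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)))


class TestReproducibilityAndPersistence:
    def test_same_seed_same_model_outputs(self):
        corpus = make_synthetic_corpus(
            CorpusSpec(n_articles=120, separation="high", vocab_size=100, seed=3)
        )
        spec = EnsembleSpec(seed=3, adaboost_rounds=3)
        b1 = train_bundle(corpus, spec)
        b2 = train_bundle(corpus, spec)
        p1 = b1.score_records(corpus.records[:20])
        p2 = b2.score_records(corpus.records[:20])
        assert (p1 == p2).all()
        assert b1.report == b2.report

    def test_bundle_round_trip(self, tmp_path):
        corpus = make_synthetic_corpus(
            CorpusSpec(n_articles=100, separation="high", vocab_size=100, seed=4)
        )
        bundle = train_bundle(corpus, EnsembleSpec(seed=4, adaboost_rounds=2))
        path = tmp_path / "model.joblib"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        got = loaded.score_records(corpus.records[:10])
        want = bundle.score_records(corpus.records[:10])
        assert (got == want).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            LabeledCorpus([ArticleRecord("1")], [RIGOR, NONRIGOR])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            LabeledCorpus([ArticleRecord("1")], ["maybe"])
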