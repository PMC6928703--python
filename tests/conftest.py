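import pytest

from litcurate.article_store import vectorize_corpus
from litcurate.eqrm import split_corpus
from litcurate.fixtures import (
    CorpusSpec,
    make_synthetic_corpus,
    make_terminology_fixture,
)
from litcurate.terminology import load_terminology


@pytest.fixture(scope="session")
def demo_store():
    """The packaged demo terminology (scenario concepts + distractors)."""
    from importlib import resources

    path = resources.files("litcurate.data").joinpath("terminology_demo.json")
    return load_terminology(str(path))


@pytest.fixture(scope="session")
def terminology_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("term") / "terminology.json"
    make_terminology_fixture(path)
    return path


@pytest.fixture(scope="session")
def small_corpus():
    """Well-separated 400-article corpus shared across classifier tests."""
    return make_synthetic_corpus(
        CorpusSpec(n_articles=400, separation="high", vocab_size=150, seed=13)
    )


@pytest.fixture(scope="session")
def small_split(small_corpus):
    """Featurized 0.7 split of the small corpus: (X_train, y_train, X_test, y_test)."""
    train, test = split_corpus(small_corpus, 0.7, seed=13)
    _, vec = vectorize_corpus(train.records)
    return (
        vec.transform(train.records),
        train.labels,
        vec.transform(test.records),
        test.labels,
    )
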