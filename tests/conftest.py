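import pytest

from healthmentions.parsing import RuleBasedBackend
from healthmentions.pipeline import datasets_from_corpus
from healthmentions.synth import CorpusSpec, IssueSpec, generate, gold_standard_specs

SYND_TERMS = [
    "cancer",
    "depression",
    "hypertension",
    "high blood pressure",
    "leukemia",
    "asthma",
]


@pytest.fixture(scope="session")
def backend():
    return RuleBasedBackend()


@pytest.fixture(scope="session")
def gold_corpus():
    """Four-issue corpus mirroring the reference gold-standard class table."""
    return generate(CorpusSpec(issues=gold_standard_specs(), seed=11))


@pytest.fixture(scope="session")
def gold_datasets(gold_corpus):
    return datasets_from_corpus(gold_corpus, "gold")


@pytest.fixture(scope="session")
def planted_corpus():
    """4 train issues x 800 posts + a 5th held-out issue, strong signal."""
    issues = tuple(
        IssueSpec(i, 800, 0.25, 0.15, 0.60, signal_strength=0.9,
                  disagreement_rate=0.1)
        for i in ("cancer", "depression", "hypertension", "leukemia")
    ) + (
        IssueSpec("asthma", 800, 0.30, 0.10, 0.60, signal_strength=0.9,
                  disagreement_rate=0.1),
    )
    return generate(CorpusSpec(issues=issues, seed=5))


@pytest.fixture(scope="session")
def planted_datasets(planted_corpus):
    return datasets_from_corpus(planted_corpus, "gold")
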