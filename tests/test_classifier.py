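import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from healthmentions.annotation import ClassLabel
from healthmentions.classifier import (
    MnbModel,
    log_joint,
    rank_features,
    score,
    train,
)

POS, NEG = ClassLabel.POSITIVE, ClassLabel.NEGATIVE


def bayes_posterior_oracle(docs, labels, alpha, bag):
    """Exact-fraction multinomial Bayes table, computed independently."""
    classes = (POS, NEG)
    vocab = sorted({f for d in docs for f in d})
    post = {}
    for c in classes:
        idx = [i for i, l in enumerate(labels) if l is c]
        prior = Fraction(len(idx), len(docs))
        total = sum(sum(docs[i].values()) for i in idx)
        p = prior
        for f, cnt in bag.items():
            if f not in vocab:
                continue
            nf = sum(docs[i][f] for i in idx)
            cond = Fraction(nf + alpha, total + alpha * len(vocab))
            p *= cond**cnt
        post[c] = p
    return post[POS] / (post[POS] + post[NEG])


def random_corpus(rng, max_docs=10, max_vocab=5):
    vocab = list("abcde")[: rng.integers(1, max_vocab + 1)]
    n = int(rng.integers(2, max_docs + 1))
    docs, labels = [], []
    for i in range(n):
        # guarantee both classes
        labels.append(POS if i % 2 == 0 else NEG)
        docs.append(
            Counter(
                {f: int(rng.integers(0, 4)) for f in vocab if rng.random() < 0.8}
            )
        )
    docs = [+d for d in docs]
    return docs, labels, vocab


class TestTrain:
    def test_symmetric_corpus_gives_uniform_priors(self):
        bags = [
            (Counter({"a": 1}), POS),
            (Counter({"b": 1}), POS),
            (Counter({"a": 1}), NEG),
            (Counter({"b": 1}), NEG),
        ]
        m = train(bags)
        assert math.isclose(math.exp(m.prior_log[POS]), 0.5)
        assert math.isclose(math.exp(m.prior_log[NEG]), 0.5)

    def test_hand_computed_conditional(self):
        # positive doc "a a b", negative doc "b"; alpha=1, vocab={a,b}
        bags = [(Counter({"a": 2, "b": 1}), POS), (Counter({"b": 1}), NEG)]
        m = train(bags, alpha=1.0)
        assert math.isclose(math.exp(m.cond_log[POS]["a"]), (2 + 1) / (3 + 2))
        assert math.isclose(math.exp(m.cond_log[POS]["b"]), (1 + 1) / (3 + 2))
        assert math.isclose(math.exp(m.cond_log[NEG]["a"]), (0 + 1) / (1 + 2))

    def test_large_alpha_approaches_uniform(self):
        bags = [(Counter({"a": 5}), POS), (Counter({"b": 1}), NEG)]
        m = train(bags, alpha=1e9)
        for c in (POS, NEG):
            for f in ("a", "b"):
                assert math.isclose(
                    math.exp(m.cond_log[c][f]), 0.5, rel_tol=1e-6
                )

    def test_conditionals_normalize_per_class(self):
        rng = np.random.default_rng(0)
        docs, labels, _ = random_corpus(rng)
        m = train(list(zip(docs, labels)), alpha=0.7)
        for c in (POS, NEG):
            assert math.isclose(
                sum(math.exp(v) for v in m.cond_log[c].values()), 1.0,
                abs_tol=1e-9,
            )

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="both classes"):
            train([(Counter({"a": 1}), POS)])

    def test_nonpositive_alpha_fatal(self):
        bags = [(Counter({"a": 1}), POS), (Counter({"a": 1}), NEG)]
        with pytest.raises(ValueError):
            train(bags, alpha=0)


class TestScore:
    def test_empty_bag_returns_prior(self):
        bags = [(Counter({"a": 1}), POS)] * 3 + [(Counter({"a": 1}), NEG)]
        m = train(bags)
        assert math.isclose(score(m, Counter()), 0.75)

    def test_symmetric_model_and_bag_gives_half(self):
        bags = [(Counter({"a": 1}), POS), (Counter({"b": 1}), NEG)]
        m = train(bags)
        assert math.isclose(score(m, Counter({"a": 1, "b": 1})), 0.5)

    def test_matches_brute_force_bayes_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            docs, labels, vocab = random_corpus(rng)
            m = train(list(zip(docs, labels)), alpha=1)
            bag = Counter(
                {f: int(rng.integers(0, 3)) for f in vocab + ["zz_oov"]}
            )
            bag = +bag
            expected = bayes_posterior_oracle(docs, labels, 1, bag)
            got = score(m, bag)
            if 0 < expected < 1:
                assert abs(
                    math.log(got) - math.log(float(expected))
                ) < 1e-12

    def test_posterior_normalizes_the_log_joint(self):
        rng = np.random.default_rng(7)
        docs, labels, vocab = random_corpus(rng)
        m = train(list(zip(docs, labels)))
        bag = Counter({vocab[0]: 2})
        lj = log_joint(m, bag)
        p = score(m, bag)
        assert 0.0 <= p <= 1.0
        # posterior odds equal the joint odds
        assert math.isclose(
            math.log(p / (1 - p)), lj[POS] - lj[NEG], abs_tol=1e-9
        )

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        docs, labels, vocab = random_corpus(rng)
        swap = {POS: NEG, NEG: POS}
        m1 = train(list(zip(docs, labels)))
        m2 = train([(d, swap[l]) for d, l in zip(docs, labels)])
        bag = Counter({f: 1 for f in vocab})
        assert math.isclose(score(m1, bag), 1 - score(m2, bag), abs_tol=1e-12)

    def test_duplicating_every_document_leaves_model_unchanged(self):
        # priors are count ratios (exactly invariant); conditionals are
        # invariant up to the smoothing pseudo-counts, so the check uses a
        # vanishing alpha
        rng = np.random.default_rng(9)
        docs, labels, _ = random_corpus(rng)
        m1 = train(list(zip(docs, labels)), alpha=1e-9)
        m2 = train(
            list(zip(docs + docs, labels + labels)), alpha=1e-9
        )
        assert m1.prior_log == pytest.approx(m2.prior_log, abs=0)
        for c in (POS, NEG):
            for f in m1.vocab:
                assert math.isclose(
                    math.exp(m1.cond_log[c][f]),
                    math.exp(m2.cond_log[c][f]),
                    abs_tol=1e-6,
                )

    def test_oov_features_ignored(self):
        bags = [(Counter({"a": 1}), POS), (Counter({"b": 1}), NEG)]
        m = train(bags)
        assert score(m, Counter({"a": 1})) == score(
            m, Counter({"a": 1, "unseen": 5})
        )


class TestRankFeatures:
    def test_positive_only_feature_outranks_balanced_one(self):
        bags = [
            (Counter({"hot": 2, "both": 1}), POS),
            (Counter({"both": 1}), NEG),
        ]
        ranked = rank_features(train(bags), 2)
        assert ranked[0] == "hot"

    def test_uniform_features_tie_break_lexicographically(self):
        bags = [
            (Counter({"b": 1, "a": 1, "c": 1}), POS),
            (Counter({"b": 1, "a": 1, "c": 1}), NEG),
        ]
        assert rank_features(train(bags), 3) == ["a", "b", "c"]

    def test_k_larger_than_vocab_fatal(self):
        bags = [(Counter({"a": 1}), POS), (Counter({"b": 1}), NEG)]
        with pytest.raises(ValueError):
            rank_features(train(bags), 3)


class TestSerializationAndOracle:
    def test_json_roundtrip_preserves_scores(self, tmp_path):
        rng = np.random.default_rng(21)
        docs, labels, vocab = random_corpus(rng)
        m = train(list(zip(docs, labels)), alpha=0.5)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = MnbModel.load(path)
        bag = Counter({vocab[0]: 1})
        assert math.isclose(score(m, bag), score(m2, bag), abs_tol=1e-12)
        assert m2.alpha == 0.5

    def test_agrees_with_sklearn_multinomial_nb(self):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        rng = np.random.default_rng(13)
        vocab = list("abcde")
        X = rng.integers(0, 4, size=(20, 5))
        y = np.array([0, 1] * 10)
        bags = [
            (Counter({f: int(x) for f, x in zip(vocab, row) if x}), POS if yi else NEG)
            for row, yi in zip(X, y)
        ]
        m = train(bags, alpha=1.0)
        clf = sklearn_nb.MultinomialNB(alpha=1.0).fit(X, y)
        probs = clf.predict_proba(X)[:, 1]
        ours = [score(m, b) for b, _ in bags]
        assert np.allclose(ours, probs, atol=1e-10)
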