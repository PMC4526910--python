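import math

import numpy as np
import pytest

from healthmentions.annotation import ClassLabel, LabeledTweet, OptionLabel
from healthmentions.corpus_io import TweetRecord
from healthmentions.evaluation import (
    ExperimentSpec,
    pr_points,
    precision_at_recall,
    run_experiment,
    stratified_splits,
)

POS, NEG = ClassLabel.POSITIVE, ClassLabel.NEGATIVE


def auprc_oracle(scores, labels):
    """O(n^2) recount: one prefix per distinct score threshold, exact."""
    from fractions import Fraction

    n_pos = sum(l is POS for l in labels)
    points = []
    ap = Fraction(0)
    prev_tp = 0
    for t in sorted(set(scores), reverse=True):
        sel = [i for i in range(len(scores)) if scores[i] >= t]
        tp = sum(labels[i] is POS for i in sel)
        points.append((tp / n_pos, tp / len(sel)))
        ap += Fraction((tp - prev_tp) * tp, len(sel) * n_pos)
        prev_tp = tp
    return points, float(ap)


def make_labeled(n_pos, n_neg, issue="x", start=0):
    out = []
    for i in range(n_pos + n_neg):
        cls = POS if i < n_pos else NEG
        opt = OptionLabel.AUTHOR if cls is POS else OptionLabel.METAPHOR
        out.append(
            LabeledTweet(
                tweet=TweetRecord(id=f"{issue}{start + i}", text="t"),
                issue_id=issue,
                cls=cls,
                policy="gold",
                options=(opt, opt),
                resolved_option=opt,
            )
        )
    return out


class TestPrPoints:
    def test_perfect_ranking_gives_auprc_one(self):
        curve = pr_points([0.9, 0.8, 0.2, 0.1], [POS, POS, NEG, NEG])
        assert curve.auprc == 1.0

    def test_constant_scores_give_prevalence(self):
        curve = pr_points([0.5] * 10, [POS] * 3 + [NEG] * 7)
        assert curve.auprc == 0.3
        assert curve.points == ((1.0, 0.3),)

    def test_worked_four_item_example(self):
        curve = pr_points([0.9, 0.8, 0.7, 0.6], [POS, NEG, POS, NEG])
        assert math.isclose(curve.auprc, (1 * 1 + (2 / 3) * 1) / 2)
        assert curve.points == ((0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            labels = [POS if rng.random() < 0.4 else NEG for _ in range(n)]
            if not any(l is POS for l in labels):
                labels[0] = POS
            # coarse grid forces plenty of ties
            scores = [float(rng.integers(0, 6)) / 5 for _ in range(n)]
            curve = pr_points(scores, labels)
            exp_points, exp_ap = auprc_oracle(scores, labels)
            assert curve.auprc == exp_ap
            assert list(curve.points) == exp_points

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        scores = list(rng.random(40))
        labels = [POS if rng.random() < 0.3 else NEG for _ in range(40)]
        labels[0] = POS
        a = pr_points(scores, labels).auprc
        b = pr_points([math.exp(3 * s) for s in scores], labels).auprc
        assert a == b

    def test_permutation_invariant_for_distinct_scores(self):
        rng = np.random.default_rng(6)
        scores = list(np.linspace(0, 1, 30))
        labels = [POS if rng.random() < 0.5 else NEG for _ in range(30)]
        labels[0] = POS
        perm = rng.permutation(30)
        a = pr_points(scores, labels).auprc
        b = pr_points(
            [scores[i] for i in perm], [labels[i] for i in perm]
        ).auprc
        assert math.isclose(a, b, abs_tol=1e-15)

    def test_no_positives_fatal(self):
        with pytest.raises(ValueError, match="no positive"):
            pr_points([0.5, 0.4], [NEG, NEG])

    def test_recalls_non_decreasing(self):
        rng = np.random.default_rng(8)
        scores = [float(rng.integers(0, 4)) for _ in range(25)]
        labels = [POS if rng.random() < 0.5 else NEG for _ in range(25)]
        labels[0] = POS
        recalls = [r for r, _ in pr_points(scores, labels).points]
        assert recalls == sorted(recalls)


class TestPrecisionAtRecall:
    def test_perfect_curve(self):
        curve = pr_points([0.9, 0.8, 0.2], [POS, POS, NEG])
        assert precision_at_recall(curve, 0.4) == 1.0

    def test_four_item_example_at_half_recall(self):
        curve = pr_points([0.9, 0.8, 0.7, 0.6], [POS, NEG, POS, NEG])
        assert precision_at_recall(curve, 0.5) == 1.0

    def test_constant_scores_any_recall_gives_prevalence(self):
        curve = pr_points([1.0] * 10, [POS] * 4 + [NEG] * 6)
        for r in (0.1, 0.5, 1.0):
            assert precision_at_recall(curve, r) == 0.4

    def test_unachievable_recall_fatal(self):
        curve = pr_points([0.9], [POS])
        with pytest.raises(ValueError):
            precision_at_recall(curve, 1.5)


class TestStratifiedSplits:
    def test_exact_class_proportions(self):
        ds = make_labeled(10, 10)
        for tr, te in stratified_splits(ds, n_reps=5, train_frac=0.8, seed=1):
            assert sum(lt.cls is POS for lt in tr) == 8
            assert sum(lt.cls is NEG for lt in tr) == 8
            assert len(te) == 4

    def test_same_seed_reproduces_splits(self):
        ds = make_labeled(7, 13)
        a = stratified_splits(ds, 3, 0.8, seed=9)
        b = stratified_splits(ds, 3, 0.8, seed=9)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert [t.tweet.id for t in tra] == [t.tweet.id for t in trb]
            assert [t.tweet.id for t in tea] == [t.tweet.id for t in teb]

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = make_labeled(9, 14)
        all_ids = {lt.tweet.id for lt in ds}
        for tr, te in stratified_splits(ds, 6, 0.75, seed=4):
            tr_ids = {t.tweet.id for t in tr}
            te_ids = {t.tweet.id for t in te}
            assert tr_ids | te_ids == all_ids
            assert not tr_ids & te_ids

    def test_tiny_class_fatal(self):
        ds = make_labeled(1, 10)
        with pytest.raises(ValueError, match="need >= 2"):
            stratified_splits(ds, 2, 0.8, 0)


class TestExperimentSpec:
    def test_hoc_requires_equal_issue_sets(self):
        with pytest.raises(ValueError):
            ExperimentSpec(frozenset("a"), frozenset("b"), "HOC-1")

    def test_hec_overlap_is_fatal(self):
        with pytest.raises(ValueError, match="disjoint"):
            ExperimentSpec(
                frozenset({"a", "b"}), frozenset({"b", "c"}), "HEC-N"
            )

    def test_single_mode_requires_one_train_issue(self):
        with pytest.raises(ValueError):
            ExperimentSpec(
                frozenset({"a", "b"}), frozenset({"a", "b"}), "HOC-1"
            )


class TestRunExperiment:
    def test_hoc1_on_separable_issue_reaches_one(self, backend):
        from healthmentions.pipeline import datasets_from_corpus
        from healthmentions.synth import CorpusSpec, IssueSpec, generate

        corpus = generate(
            CorpusSpec(
                issues=(
                    IssueSpec(
                        "cancer", 200, 0.3, 0.2, 0.5,
                        signal_strength=1.0, disagreement_rate=0.0,
                    ),
                ),
                seed=3,
            )
        )
        ds = datasets_from_corpus(corpus, "gold")
        spec = ExperimentSpec(
            frozenset({"cancer"}), frozenset({"cancer"}), "HOC-1",
            n_reps=5, seed=0,
        )
        res = run_experiment(spec, ds, ["cancer"], backend)
        assert res.auprc_mean == 1.0
        assert len(res.per_rep) == 5

    def test_n_reps_respected(self, gold_datasets, backend):
        small = {"leukemia": gold_datasets["leukemia"][:120]}
        spec = ExperimentSpec(
            frozenset({"leukemia"}), frozenset({"leukemia"}), "HOC-1",
            n_reps=30, seed=2,
        )
        res = run_experiment(spec, small, ["leukemia"], backend)
        assert len(res.per_rep) == 30

    def test_budget_subsampling_controls_train_size(self, gold_datasets, backend):
        small = {"leukemia": gold_datasets["leukemia"][:200]}
        spec = ExperimentSpec(
            frozenset({"leukemia"}), frozenset({"leukemia"}), "HOC-1",
            n_reps=2, seed=2,
        )
        res = run_experiment(
            spec, small, ["leukemia"], backend, train_budget=50
        )
        assert res.n_train == 50

    def test_excessive_budget_fatal(self, gold_datasets, backend):
        small = {"leukemia": gold_datasets["leukemia"][:50]}
        spec = ExperimentSpec(
            frozenset({"leukemia"}), frozenset({"leukemia"}), "HOC-1",
            n_reps=1, seed=2,
        )
        with pytest.raises(ValueError, match="budget"):
            run_experiment(
                spec, small, ["leukemia"], backend, train_budget=10_000
            )
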