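"""Precision-recall evaluation and the cross-issue experiment harness.

Ranked evaluation uses tie-aware average precision: posts are sorted by
score descending, tied scores are walked as one block, and a
(recall, precision) point is emitted after each block.  AUPRC is the sum,
over positive posts, of the precision at the end of their block, divided
by the number of positives.  Evaluating a tie block atomically makes the
constant scorer's AUPRC equal the positive prevalence — the natural
chance baseline for an imbalanced class ratio — instead of the optimistic
value linear interpolation would give.

Four experiment modes probe how a mention classifier generalizes across
health issues:

* ``HOC-1`` / ``HOC-N`` — homogeneous: train and test on the same issue
  (or same set of issues), via repeated stratified 80/20 splits.
* ``HEC-1`` / ``HEC-N`` — heterogeneous: train on one (or several)
  issue(s), test on *disjoint* issues.  The full labeled set of each test
  issue is scored, since no post can leak from train to test.

Each experiment runs ``n_reps`` (default 30) replicates with replicate
seeds derived as ``seed + rep``, and reports the mean and sample SD of
AUPRC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .annotation import ClassLabel, LabeledTweet
from .classifier import score, train
from .features import FeatureBag, extract
from .parsing import ParserBackend, RuleBasedBackend

__all__ = [
    "PRCurve",
    "ExperimentSpec",
    "ExperimentResult",
    "pr_points",
    "precision_at_recall",
    "stratified_splits",
    "run_experiment",
    "MODES",
]

MODES = ("HOC-1", "HOC-N", "HEC-1", "HEC-N")


@dataclass(frozen=True)
class PRCurve:
    points: tuple[tuple[float, float], ...]  # (recall, precision)
    auprc: float


def pr_points(
    scores: Sequence[float], labels: Sequence[ClassLabel]
) -> PRCurve:
    """Tie-aware PR curve and average precision for one ranked test set."""
    if len(scores) != len(labels) or not scores:
        raise ValueError("scores and labels must be equal-length, non-empty")
    n_pos = sum(l is ClassLabel.POSITIVE for l in labels)
    if n_pos == 0:
        raise ValueError("AUPRC undefined: no positive posts in test set")
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    points: list[tuple[float, float]] = []
    # AP accumulated in exact rational arithmetic so that algebraic laws
    # (perfect ranking -> 1, all tied -> prevalence) hold exactly in the
    # returned float
    ap = Fraction(0)
    tp = seen = 0
    i = 0
    while i < len(order):
        j = i
        block_tp = 0
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] is ClassLabel.POSITIVE:
                block_tp += 1
            j += 1
        seen += j - i
        tp += block_tp
        points.append((tp / n_pos, tp / seen))
        ap += Fraction(block_tp * tp, seen * n_pos)
        i = j
    return PRCurve(points=tuple(points), auprc=float(ap))


def precision_at_recall(curve: PRCurve, r: float) -> float:
    """Precision at the first curve point whose recall >= r (step curve)."""
    if not 0 < r <= curve.points[-1][0]:
        raise ValueError(
            f"recall {r} not achievable (max {curve.points[-1][0]})"
        )
    for recall, precision in curve.points:
        if recall >= r:
            return precision
    raise AssertionError("unreachable")  # pragma: no cover


def stratified_splits(
    ds: Sequence[LabeledTweet],
    n_reps: int = 30,
    train_frac: float = 0.8,
    seed: int = 0,
) -> list[tuple[list[LabeledTweet], list[LabeledTweet]]]:
    """``n_reps`` stratified train/test partitions of a labeled dataset.

    Per replicate and class: shuffle with the replicate seed, assign
    ``floor(train_frac * n_class)`` posts to train and the rest to test.
    Train and test are disjoint and exhaustive in every replicate.
    """
    by_class: dict[ClassLabel, list[LabeledTweet]] = {}
    for lt in ds:
        by_class.setdefault(lt.cls, []).append(lt)
    for cls, members in by_class.items():
        if len(members) < 2:
            raise ValueError(
                f"class {cls.value!r} has {len(members)} member(s); need >= 2"
            )
    out = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        tr: list[LabeledTweet] = []
        te: list[LabeledTweet] = []
        for cls in sorted(by_class, key=lambda c: c.value):
            members = by_class[cls]
            idx = rng.permutation(len(members))
            cut = math.floor(train_frac * len(members))
            tr.extend(members[i] for i in idx[:cut])
            te.extend(members[i] for i in idx[cut:])
        out.append((tr, te))
    return out


@dataclass(frozen=True)
class ExperimentSpec:
    """One cross-issue experiment: which issues train, which test."""

    train_issues: frozenset[str]
    test_issues: frozenset[str]
    mode: str
    n_reps: int = 30
    train_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        single = self.mode.endswith("-1")
        if single and len(self.train_issues) != 1:
            raise ValueError(f"{self.mode} requires exactly one train issue")
        if not single and len(self.train_issues) < 2:
            raise ValueError(f"{self.mode} requires > 1 train issue")
        if self.mode.startswith("HOC"):
            if self.train_issues != self.test_issues:
                raise ValueError("HOC modes require train issues == test issues")
        else:
            if self.train_issues & self.test_issues:
                raise ValueError(
                    "HEC modes require disjoint train/test issues "
                    f"(overlap: {sorted(self.train_issues & self.test_issues)})"
                )


@dataclass(frozen=True)
class ExperimentResult:
    auprc_mean: float
    auprc_sd: float
    per_rep: tuple[float, ...]
    n_train: int
    curve: PRCurve  # PR curve of the first replicate


def _budget_subsample(
    pool: Sequence[LabeledTweet], budget: int, rng: np.random.Generator
) -> list[LabeledTweet]:
    """Class-stratified subsample of ``pool`` to exactly ``budget`` posts."""
    if budget >= len(pool):
        return list(pool)
    by_class: dict[ClassLabel, list[LabeledTweet]] = {}
    for lt in pool:
        by_class.setdefault(lt.cls, []).append(lt)
    # largest-remainder allocation of the budget across classes
    quotas = {
        c: budget * len(m) / len(pool) for c, m in by_class.items()
    }
    alloc = {c: math.floor(q) for c, q in quotas.items()}
    rem = budget - sum(alloc.values())
    for c in sorted(quotas, key=lambda c: (alloc[c] - quotas[c], c.value)):
        if rem <= 0:
            break
        alloc[c] += 1
        rem -= 1
    out: list[LabeledTweet] = []
    for cls in sorted(by_class, key=lambda c: c.value):
        members = by_class[cls]
        idx = rng.permutation(len(members))[: alloc[cls]]
        out.extend(members[i] for i in idx)
    return out


def run_experiment(
    spec: ExperimentSpec,
    datasets: Mapping[str, Sequence[LabeledTweet]],
    issue_terms: Sequence[str],
    backend: ParserBackend | None = None,
    alpha: float = 1.0,
    train_budget: int | None = None,
) -> ExperimentResult:
    """Run one HOC/HEC experiment end to end.

    Per replicate: take the stratified ``train_frac`` side of the training
    issues' pooled posts (subsampled to ``train_budget`` if given), fit the
    classifier, score the test posts — the replicate's held-out slice for
    HOC, the full labeled set of the disjoint test issues for HEC — and
    compute AUPRC.  Feature bags are extracted once up front (extraction is
    pure) and reused across replicates.
    """
    backend = backend or RuleBasedBackend()
    missing = (spec.train_issues | spec.test_issues) - set(datasets)
    if missing:
        raise KeyError(f"datasets missing for issues: {sorted(missing)}")

    bag_cache: dict[int, FeatureBag] = {}

    def bag_of(lt: LabeledTweet) -> FeatureBag:
        key = id(lt)
        if key not in bag_cache:
            bag_cache[key] = extract(lt.tweet.text, issue_terms, backend)
        return bag_cache[key]

    train_pool = [
        lt for issue in sorted(spec.train_issues) for lt in datasets[issue]
    ]
    if spec.mode.startswith("HEC"):
        test_pool = [
            lt for issue in sorted(spec.test_issues) for lt in datasets[issue]
        ]
        test_bags = [bag_of(lt) for lt in test_pool]
        test_labels = [lt.cls for lt in test_pool]

    splits = stratified_splits(
        train_pool, spec.n_reps, spec.train_frac, spec.seed
    )
    per_rep: list[float] = []
    n_train_used = 0
    first_curve: PRCurve | None = None
    for rep, (tr, held_out) in enumerate(splits):
        rng = np.random.default_rng(spec.seed + rep)
        if train_budget is not None:
            if train_budget > len(tr):
                raise ValueError(
                    f"train_budget {train_budget} exceeds available "
                    f"training posts ({len(tr)})"
                )
            tr = _budget_subsample(tr, train_budget, rng)
        n_train_used = len(tr)
        model = train([(bag_of(lt), lt.cls) for lt in tr], alpha=alpha)
        if spec.mode.startswith("HOC"):
            scores = [score(model, bag_of(lt)) for lt in held_out]
            labels = [lt.cls for lt in held_out]
        else:
            scores = [score(model, b) for b in test_bags]
            labels = test_labels
        curve = pr_points(scores, labels)
        if first_curve is None:
            first_curve = curve
        per_rep.append(curve.auprc)
    arr = np.asarray(per_rep)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return ExperimentResult(
        auprc_mean=float(arr.mean()),
        auprc_sd=sd,
        per_rep=tuple(per_rep),
        n_train=n_train_used,
        curve=first_curve,
    )
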