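"""Multinomial Naive Bayes over feature bags, written out in full.

The model is the textbook multinomial event model with additive
(Lindstone/Laplace) smoothing: for class :math:`c` and feature :math:`f`,

.. math::

    \\hat P(c) = N_c / N, \\qquad
    \\hat P(f \\mid c) = \\frac{n_{cf} + \\alpha}{n_c + \\alpha |V|}

where :math:`n_{cf}` is the total count of *f* in class *c* documents,
:math:`n_c` the total feature count in class *c*, and *V* the training
vocabulary.  Scoring runs in log space and normalizes over the two
classes, so posteriors sum to 1 by construction.  Features unseen in
training are ignored at scoring time, which keeps train and test
vocabularies decoupled when transferring a classifier across health
issues.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .annotation import ClassLabel
from .features import FeatureBag

__all__ = ["MnbModel", "train", "score", "score_many", "rank_features"]

_CLASSES = (ClassLabel.POSITIVE, ClassLabel.NEGATIVE)


@dataclass(frozen=True)
class MnbModel:
    """Fitted parameters: log priors, smoothed log conditionals, vocab."""

    prior_log: dict[ClassLabel, float]
    cond_log: dict[ClassLabel, dict[str, float]]
    vocab: frozenset[str]
    alpha: float

    def save(self, path: str | Path) -> None:
        data = {
            "alpha": self.alpha,
            "prior_log": {c.value: v for c, v in self.prior_log.items()},
            "cond_log": {
                c.value: dict(sorted(m.items()))
                for c, m in self.cond_log.items()
            },
        }
        Path(path).write_text(
            json.dumps(data, indent=1, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "MnbModel":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        cond = {
            ClassLabel(c): dict(m) for c, m in data["cond_log"].items()
        }
        return cls(
            prior_log={
                ClassLabel(c): v for c, v in data["prior_log"].items()
            },
            cond_log=cond,
            vocab=frozenset(next(iter(cond.values()), {})),
            alpha=data["alpha"],
        )


def train(
    bags: Sequence[tuple[FeatureBag, ClassLabel]], alpha: float = 1.0
) -> MnbModel:
    """Fit the model.  Both classes must be present; ``alpha > 0``."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    labels = {cls for _, cls in bags}
    if labels != set(_CLASSES):
        raise ValueError(
            f"training set must contain both classes, got {sorted(l.value for l in labels)}"
        )
    n_docs = len(bags)
    class_counts: dict[ClassLabel, Counter] = {c: Counter() for c in _CLASSES}
    doc_counts: dict[ClassLabel, int] = {c: 0 for c in _CLASSES}
    for bag, cls in bags:
        doc_counts[cls] += 1
        class_counts[cls].update(bag)
    vocab = frozenset().union(*(set(c) for c in class_counts.values()))
    prior_log = {
        c: math.log(doc_counts[c] / n_docs) for c in _CLASSES
    }
    cond_log: dict[ClassLabel, dict[str, float]] = {}
    v = len(vocab)
    for c in _CLASSES:
        if v == 0:  # all training bags empty: no conditionals to estimate
            cond_log[c] = {}
            continue
        total = sum(class_counts[c].values())
        denom = math.log(total + alpha * v)
        cond_log[c] = {
            f: math.log(class_counts[c][f] + alpha) - denom for f in vocab
        }
    return MnbModel(
        prior_log=prior_log, cond_log=cond_log, vocab=vocab, alpha=alpha
    )


def log_joint(model: MnbModel, bag: FeatureBag) -> dict[ClassLabel, float]:
    """Unnormalized log P(c, bag); out-of-vocabulary features are dropped."""
    out: dict[ClassLabel, float] = {}
    for c in _CLASSES:
        cond = model.cond_log[c]
        s = model.prior_log[c]
        for f, n in bag.items():
            if f in model.vocab:
                s += n * cond[f]
        out[c] = s
    return out


def score(model: MnbModel, bag: FeatureBag) -> float:
    """Posterior probability that the post is a personal health mention."""
    lj = log_joint(model, bag)
    a, b = lj[ClassLabel.POSITIVE], lj[ClassLabel.NEGATIVE]
    m = max(a, b)
    ea, eb = math.exp(a - m), math.exp(b - m)
    return ea / (ea + eb)


def score_many(
    model: MnbModel, bags: Iterable[FeatureBag]
) -> list[float]:
    return [score(model, bag) for bag in bags]


def rank_features(model: MnbModel, k: int) -> list[str]:
    """The *k* features most indicative of the positive class.

    Ordered by descending log-likelihood ratio
    ``log P(f|positive) - log P(f|negative)``, ties broken
    lexicographically.
    """
    if k > len(model.vocab):
        raise ValueError(f"k={k} exceeds vocabulary size {len(model.vocab)}")
    pos = model.cond_log[ClassLabel.POSITIVE]
    neg = model.cond_log[ClassLabel.NEGATIVE]
    ranked = sorted(model.vocab, key=lambda f: (-(pos[f] - neg[f]), f))
    return ranked[:k]
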