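"""Seeded generator of synthetic dual-annotated health-mention corpora.

Real collections of health-issue posts with crowd labels are rarely
redistributable, so every stage of the pipeline is exercised against
generated corpora that reproduce the *statistical* structure the pipeline
assumes: per-issue class ratios, an author-vs-others disclosure split, a
controllable second-annotator disagreement rate, and class-indicative
surface cues (first-person pronouns and have/suffer verbs for author
posts, kin terms and third-person pronouns for posts about others,
metaphor/viewpoint/worry phrasings for negatives) planted with tunable
strength.

``signal_strength`` s interpolates between no signal and perfect
separability: each post uses a class-indicative template with probability
s and a class-neutral template otherwise.  At s = 1 the planted indicator
tokens ("i", "my" for the positive class) occur only in their class; at
s = 0 all classes draw from the same neutral templates.

Class counts are allocated exactly (largest-remainder rounding of the
class probabilities, then a seeded shuffle), not sampled, so a fixture
mirroring a printed class table reproduces its counts verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import (
    NEGATIVE_OPTIONS,
    POSITIVE_OPTIONS,
    OptionLabel,
    to_class,
)
from .corpus_io import AnnotationRecord, TweetRecord

__all__ = [
    "IssueSpec",
    "CorpusSpec",
    "SynthCorpus",
    "generate",
    "planted_signal_report",
    "gold_standard_specs",
    "PLANTED_POSITIVE_TOKENS",
    "PLANTED_NEGATIVE_TOKENS",
]

# tokens the class-indicative templates plant preferentially per class
PLANTED_POSITIVE_TOKENS = ("i", "my")
PLANTED_NEGATIVE_TOKENS = ("hope", "lol", "should")

_AUTHOR_TEMPLATES = (
    "i have {issue} and it is rough",
    "ugh my {issue} is back again !!!",
    "i am suffering from {issue} today",
    "my doctor says i have {issue} \U0001f637",
    "i got diagnosed with {issue} , wish me luck",
)
_RELATIVE_TEMPLATES = (
    "my mom has {issue} , prayers appreciated",
    "my dad is fighting {issue} , he is strong",
    "my little cousin has {issue} \U0001f622",
)
_SOMEONE_TEMPLATES = (
    "she has {issue} and she is so brave",
    "he lost his battle with {issue} last year",
    "she got diagnosed with {issue} last week",
)
_METAPHOR_TEMPLATES = (
    "this traffic is pure {issue} lol",
    "that exam was {issue} for the brain lol",
    "you are gonna give viv a {issue} lol",
)
_VIEWPOINT_TEMPLATES = (
    "more funding for {issue} research is needed",
    "the government should do more about {issue}",
    "everyone should learn the warning signs of {issue}",
)
_WORRY_TEMPLATES = (
    "hope that cough is not {issue}",
    "hope this headache does not turn into {issue} \U0001f630",
    "what if it turns out to be {issue}",
)
_NA_TEMPLATES = (
    "now hiring at the {issue} clinic apply here http://example.com/jobs",
    "win free tickets to the {issue} awareness run http://example.com/win @promo",
)
_NEUTRAL_TEMPLATES = (
    "{issue} was mentioned on the news",
    "reading about {issue} at the library",
    "that {issue} story was on tv again",
    "a new {issue} study came out",
)

_TEMPLATES: dict[OptionLabel, tuple[str, ...]] = {
    OptionLabel.AUTHOR: _AUTHOR_TEMPLATES,
    OptionLabel.RELATIVE_OR_FRIEND: _RELATIVE_TEMPLATES,
    OptionLabel.SOMEONE_ELSE: _SOMEONE_TEMPLATES,
    OptionLabel.METAPHOR: _METAPHOR_TEMPLATES,
    OptionLabel.VIEWPOINT: _VIEWPOINT_TEMPLATES,
    OptionLabel.WORRY: _WORRY_TEMPLATES,
    OptionLabel.NA: _NA_TEMPLATES,
}


@dataclass(frozen=True)
class IssueSpec:
    """Generation parameters for one health issue."""

    issue_id: str
    n_tweets: int
    p_author: float
    p_others: float
    p_negative: float
    signal_strength: float = 0.9
    disagreement_rate: float = 0.1
    term: str = ""  # keyword embedded in templates; defaults to issue_id

    def __post_init__(self) -> None:
        total = self.p_author + self.p_others + self.p_negative
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"{self.issue_id}: class probabilities sum to {total}, not 1"
            )
        if not 0 <= self.disagreement_rate <= 1:
            raise ValueError("disagreement_rate must be in [0, 1]")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if not self.term:
            object.__setattr__(self, "term", self.issue_id.replace("_", " "))

    @classmethod
    def from_class_counts(
        cls,
        issue_id: str,
        n_positive: int,
        n_negative: int,
        author_frac: float = 0.5,
        **kwargs,
    ) -> "IssueSpec":
        """Spec whose exact allocation yields the given class counts."""
        n = n_positive + n_negative
        p_pos = n_positive / n
        return cls(
            issue_id=issue_id,
            n_tweets=n,
            p_author=p_pos * author_frac,
            p_others=p_pos * (1 - author_frac),
            p_negative=n_negative / n,
            **kwargs,
        )


@dataclass(frozen=True)
class CorpusSpec:
    issues: tuple[IssueSpec, ...]
    seed: int = 0
    shared_vocab: int = 50  # size of the class-neutral noise vocabulary
    exact: bool = True  # exact-count class allocation vs i.i.d. sampling

    def __post_init__(self) -> None:
        ids = [s.issue_id for s in self.issues]
        if len(set(ids)) != len(ids):
            raise ValueError("issue_ids must be unique")
        if all(s.n_tweets == 0 for s in self.issues):
            raise ValueError("at least one issue must have n_tweets > 0")


@dataclass(frozen=True)
class SynthCorpus:
    tweets: tuple[TweetRecord, ...]
    annotations: tuple[AnnotationRecord, ...]
    truth: dict[str, OptionLabel]  # tweet id -> true option
    issue_of: dict[str, str]  # tweet id -> issue id


def _largest_remainder(probs: Sequence[float], n: int) -> list[int]:
    quotas = [p * n for p in probs]
    alloc = [math.floor(q) for q in quotas]
    rem = n - sum(alloc)
    order = sorted(
        range(len(probs)), key=lambda i: (alloc[i] - quotas[i], i)
    )
    for i in order[:rem]:
        alloc[i] += 1
    return alloc


def _option_vector(spec: IssueSpec, rng: np.random.Generator) -> list[OptionLabel]:
    """Exact-count option labels for one issue, then a seeded shuffle."""
    n_author, n_others, n_negative = _largest_remainder(
        (spec.p_author, spec.p_others, spec.p_negative), spec.n_tweets
    )
    labels: list[OptionLabel] = [OptionLabel.AUTHOR] * n_author
    # alternate the two others options; cycle the four negative options
    others_cycle = (OptionLabel.RELATIVE_OR_FRIEND, OptionLabel.SOMEONE_ELSE)
    labels += [others_cycle[i % 2] for i in range(n_others)]
    labels += [NEGATIVE_OPTIONS[i % 4] for i in range(n_negative)]
    perm = rng.permutation(len(labels))
    return [labels[i] for i in perm]


def _sample_options(
    spec: IssueSpec, rng: np.random.Generator
) -> list[OptionLabel]:
    """i.i.d. alternative to exact allocation."""
    out = []
    for _ in range(spec.n_tweets):
        u = rng.random()
        if u < spec.p_author:
            out.append(OptionLabel.AUTHOR)
        elif u < spec.p_author + spec.p_others:
            out.append(
                OptionLabel.RELATIVE_OR_FRIEND
                if rng.random() < 0.5
                else OptionLabel.SOMEONE_ELSE
            )
        else:
            out.append(NEGATIVE_OPTIONS[rng.integers(4)])
    return out


def _render(
    option: OptionLabel,
    spec: IssueSpec,
    rng: np.random.Generator,
    vocab: int,
) -> str:
    if rng.random() < spec.signal_strength:
        pool = _TEMPLATES[option]
    else:
        pool = _NEUTRAL_TEMPLATES
    text = pool[rng.integers(len(pool))].format(issue=spec.term)
    n_noise = int(rng.integers(1, 4))
    noise = " ".join(f"w{int(rng.integers(vocab))}" for _ in range(n_noise))
    return f"{text} {noise}"


def _flip_option(
    option: OptionLabel, rng: np.random.Generator
) -> OptionLabel:
    """Uniform option from the class opposite to ``option``'s."""
    if option in POSITIVE_OPTIONS:
        pool = NEGATIVE_OPTIONS
    else:
        pool = POSITIVE_OPTIONS
    return pool[rng.integers(len(pool))]


def generate(spec: CorpusSpec) -> SynthCorpus:
    """Generate tweets, dual-plus-tiebreak annotations and ground truth.

    Annotator ``A1`` reports the true option, ``A2`` flips the mapped
    class with probability ``disagreement_rate`` (then picks a uniform
    option within the flipped class), and ``A3`` — the tiebreaker —
    reports the truth.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    tweets: list[TweetRecord] = []
    annotations: list[AnnotationRecord] = []
    truth: dict[str, OptionLabel] = {}
    issue_of: dict[str, str] = {}
    idx = 0
    for issue in spec.issues:
        if issue.n_tweets == 0:
            continue
        options = (
            _option_vector(issue, rng)
            if spec.exact
            else _sample_options(issue, rng)
        )
        for option in options:
            tid = f"t{idx:06d}"
            idx += 1
            text = _render(option, issue, rng, spec.shared_vocab)
            tweets.append(
                TweetRecord(
                    id=tid,
                    text=text,
                    lang="en",
                    has_coordinates=True,
                    has_place=False,
                )
            )
            truth[tid] = option
            issue_of[tid] = issue.issue_id
            a2 = (
                _flip_option(option, rng)
                if rng.random() < issue.disagreement_rate
                else option
            )
            annotations.append(AnnotationRecord(tid, "A1", option.value))
            annotations.append(AnnotationRecord(tid, "A2", a2.value))
            annotations.append(AnnotationRecord(tid, "A3", option.value))
    return SynthCorpus(
        tweets=tuple(tweets),
        annotations=tuple(annotations),
        truth=truth,
        issue_of=issue_of,
    )


def planted_signal_report(
    spec: CorpusSpec, corpus: SynthCorpus
) -> dict[str, dict[str, float]]:
    """Realized per-class frequencies of the planted indicator tokens.

    For each planted token, the fraction of positive-class and
    negative-class posts containing it — the empirical handle from which a
    Bayes-optimal separability bound can be computed by brute force.
    """
    import re

    word_re = re.compile(r"[a-z']+")
    n = {"positive": 0, "negative": 0}
    hits: dict[str, dict[str, int]] = {
        tok: {"positive": 0, "negative": 0}
        for tok in PLANTED_POSITIVE_TOKENS + PLANTED_NEGATIVE_TOKENS
    }
    for tweet in corpus.tweets:
        cls = to_class(corpus.truth[tweet.id]).value
        n[cls] += 1
        words = set(word_re.findall(tweet.text.lower()))
        for tok in hits:
            if tok in words:
                hits[tok][cls] += 1
    return {
        tok: {
            cls: (count[cls] / n[cls] if n[cls] else 0.0)
            for cls in ("positive", "negative")
        }
        for tok, count in hits.items()
    }


def gold_standard_specs(
    signal_strength: float = 0.9, disagreement_rate: float = 0.1
) -> tuple[IssueSpec, ...]:
    """Four-issue specs mirroring the reference gold-standard class table.

    Positive/negative counts per issue: cancer 166/697, depression
    261/461, hypertension 211/551, leukemia 436/423 (their union is the
    2000-positive-odd multi-issue training pool).  Cancer and leukemia are
    skewed toward disclosures about others, depression and hypertension
    toward the author, matching the qualitative disclosure profiles the
    four issues were chosen for.
    """
    rows = (
        ("cancer", 166, 697, 0.35),
        ("depression", 261, 461, 0.75),
        ("hypertension", 211, 551, 0.70),
        ("leukemia", 436, 423, 0.30),
    )
    return tuple(
        IssueSpec.from_class_counts(
            issue_id,
            n_pos,
            n_neg,
            author_frac,
            signal_strength=signal_strength,
            disagreement_rate=disagreement_rate,
        )
        for issue_id, n_pos, n_neg, author_frac in rows
    )
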