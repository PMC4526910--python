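"""Label taxonomy and adjudication of dual-annotated posts.

Each post is annotated with one of seven *options* describing how the
health-issue term is used.  The options project onto a binary class:

* positive (a personal health mention): ``author``, ``relative_or_friend``,
  ``someone_else``
* negative: ``metaphor``, ``viewpoint``, ``worry``, ``na``

Two primary annotators label every post; four dataset-construction
policies resolve their (dis)agreement:

* ``gold`` — keep only posts whose two mapped classes agree.
* ``cap`` — conflict-as-positive: conflicting posts labeled positive.
* ``can`` — conflict-as-negative: conflicting posts labeled negative.
* ``tiebreak`` — a third annotator breaks the tie; the class is the
  majority of the three mapped classes.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .corpus_io import AnnotationRecord, TweetRecord

__all__ = [
    "OptionLabel",
    "ClassLabel",
    "LabeledTweet",
    "POSITIVE_OPTIONS",
    "NEGATIVE_OPTIONS",
    "POLICIES",
    "to_class",
    "group_annotations",
    "build_dataset",
    "agreement_rate",
]


class OptionLabel(str, Enum):
    AUTHOR = "author"
    RELATIVE_OR_FRIEND = "relative_or_friend"
    SOMEONE_ELSE = "someone_else"
    METAPHOR = "metaphor"
    VIEWPOINT = "viewpoint"
    WORRY = "worry"
    NA = "na"


class ClassLabel(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


POSITIVE_OPTIONS = (
    OptionLabel.AUTHOR,
    OptionLabel.RELATIVE_OR_FRIEND,
    OptionLabel.SOMEONE_ELSE,
)
NEGATIVE_OPTIONS = (
    OptionLabel.METAPHOR,
    OptionLabel.VIEWPOINT,
    OptionLabel.WORRY,
    OptionLabel.NA,
)

POLICIES = ("gold", "cap", "can", "tiebreak")


def to_class(option: OptionLabel | str) -> ClassLabel:
    """Project a 7-way option onto the binary mention class."""
    option = OptionLabel(option)
    if option in POSITIVE_OPTIONS:
        return ClassLabel.POSITIVE
    return ClassLabel.NEGATIVE


@dataclass(frozen=True)
class LabeledTweet:
    """One post with its adjudicated class and option-level provenance.

    ``options`` holds the 2 (or 3, under tiebreak) contributing option
    labels in annotator order; ``resolved_option`` is the single option
    consistent with ``cls`` used by the disclosure analysis (the first
    contributing annotator whose mapped class equals ``cls``; for a CAP/CAN
    override with no such annotator it falls back to a canonical option of
    the assigned class).
    """

    tweet: TweetRecord
    issue_id: str
    cls: ClassLabel
    policy: str
    options: tuple[OptionLabel, ...]
    resolved_option: OptionLabel

    def __post_init__(self) -> None:
        if not 2 <= len(self.options) <= 3:
            raise ValueError("provenance must list 2 or 3 option labels")


def group_annotations(
    annotations: Iterable[AnnotationRecord],
) -> "OrderedDict[str, list[OptionLabel]]":
    """Group annotation records by tweet id, preserving record order.

    The first two records per tweet are the primary annotators; a third,
    when present, is the tiebreaker.
    """
    grouped: OrderedDict[str, list[OptionLabel]] = OrderedDict()
    for rec in annotations:
        grouped.setdefault(rec.tweet_id, []).append(OptionLabel(rec.option))
    return grouped


def _resolve_option(
    cls: ClassLabel, options: Sequence[OptionLabel]
) -> OptionLabel:
    for o in options:
        if to_class(o) is cls:
            return o
    # conflict overridden by policy with no annotator on the winning side
    return (
        OptionLabel.SOMEONE_ELSE
        if cls is ClassLabel.POSITIVE
        else OptionLabel.NA
    )


def build_dataset(
    tweets: Mapping[str, TweetRecord],
    annos: Mapping[str, Sequence[OptionLabel]],
    policy: str,
    issue_id: str = "",
) -> list[LabeledTweet]:
    """Adjudicate dual annotations into a labeled dataset.

    ``annos`` maps tweet id to its option labels in annotator order: exactly
    2 primary options, plus a third for conflicted tweets when
    ``policy="tiebreak"``.  Tweets absent from ``tweets`` are fatal.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    missing_third: list[str] = []
    out: list[LabeledTweet] = []
    for tid, options in annos.items():
        if len(options) < 2:
            raise ValueError(f"tweet {tid!r} has fewer than 2 annotations")
        if tid not in tweets:
            raise KeyError(f"tweet {tid!r} has annotations but no record")
        primary = tuple(OptionLabel(o) for o in options[:2])
        c1, c2 = (to_class(o) for o in primary)
        agree = c1 is c2
        if agree:
            cls = c1
            used = primary
        elif policy == "gold":
            continue
        elif policy == "cap":
            cls = ClassLabel.POSITIVE
            used = primary
        elif policy == "can":
            cls = ClassLabel.NEGATIVE
            used = primary
        else:  # tiebreak
            if len(options) < 3:
                missing_third.append(tid)
                continue
            third = OptionLabel(options[2])
            used = primary + (third,)
            votes = [to_class(o) for o in used]
            n_pos = sum(v is ClassLabel.POSITIVE for v in votes)
            cls = ClassLabel.POSITIVE if n_pos >= 2 else ClassLabel.NEGATIVE
        out.append(
            LabeledTweet(
                tweet=tweets[tid],
                issue_id=issue_id,
                cls=cls,
                policy=policy,
                options=used,
                resolved_option=_resolve_option(cls, used),
            )
        )
    if missing_third:
        raise ValueError(
            "tiebreak requires a third annotation for conflicted tweets; "
            f"missing for ids: {sorted(missing_third)}"
        )
    return out


def agreement_rate(annos: Mapping[str, Sequence[OptionLabel]]) -> float:
    """Fraction of tweets whose two primary mapped classes agree."""
    if not annos:
        raise ValueError("no annotated tweets")
    n_agree = 0
    for tid, options in annos.items():
        if len(options) < 2:
            raise ValueError(f"tweet {tid!r} has fewer than 2 annotations")
        if to_class(options[0]) is to_class(options[1]):
            n_agree += 1
    return n_agree / len(annos)
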