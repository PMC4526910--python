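"""Glue for composing the pipeline stages and labeled-dataset file IO."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import (
    ClassLabel,
    LabeledTweet,
    OptionLabel,
    build_dataset,
    group_annotations,
)
from .corpus_io import AnnotationRecord, TweetRecord
from .synth import SynthCorpus

__all__ = [
    "datasets_from_corpus",
    "label_components",
    "write_labeled",
    "read_labeled",
]


def label_components(
    tweets: Sequence[TweetRecord],
    annotations: Iterable[AnnotationRecord],
    policy: str,
    issue_of: Mapping[str, str] | str = "",
) -> list[LabeledTweet]:
    """Adjudicate raw tweets + annotation records into a labeled dataset.

    ``issue_of`` maps tweet id to its bin issue (or is a single issue id
    applied to every tweet).
    """
    tweet_map = {t.id: t for t in tweets}
    grouped = group_annotations(annotations)
    labeled = build_dataset(tweet_map, grouped, policy)
    if isinstance(issue_of, str):
        issue = issue_of
        return [
            LabeledTweet(
                lt.tweet, issue, lt.cls, lt.policy, lt.options,
                lt.resolved_option,
            )
            for lt in labeled
        ]
    return [
        LabeledTweet(
            lt.tweet,
            issue_of.get(lt.tweet.id, ""),
            lt.cls,
            lt.policy,
            lt.options,
            lt.resolved_option,
        )
        for lt in labeled
    ]


def datasets_from_corpus(
    corpus: SynthCorpus, policy: str
) -> dict[str, list[LabeledTweet]]:
    """Per-issue labeled datasets from a generated corpus."""
    labeled = label_components(
        corpus.tweets, corpus.annotations, policy, corpus.issue_of
    )
    out: dict[str, list[LabeledTweet]] = {}
    for lt in labeled:
        out.setdefault(lt.issue_id, []).append(lt)
    return out


def write_labeled(labeled: Sequence[LabeledTweet], path: str | Path) -> None:
    """Write a labeled dataset as JSONL (one object per post)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for lt in labeled:
            fh.write(
                json.dumps(
                    {
                        "id": lt.tweet.id,
                        "text": lt.tweet.text,
                        "lang": lt.tweet.lang,
                        "has_coordinates": lt.tweet.has_coordinates,
                        "has_place": lt.tweet.has_place,
                        "place_country": lt.tweet.place_country,
                        "issue_id": lt.issue_id,
                        "class": lt.cls.value,
                        "policy": lt.policy,
                        "options": [o.value for o in lt.options],
                        "resolved_option": lt.resolved_option.value,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_labeled(path: str | Path) -> list[LabeledTweet]:
    out: list[LabeledTweet] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(
                LabeledTweet(
                    tweet=TweetRecord(
                        id=obj["id"],
                        text=obj["text"],
                        lang=obj.get("lang", ""),
                        has_coordinates=obj.get("has_coordinates", False),
                        has_place=obj.get("has_place", False),
                        place_country=obj.get("place_country", ""),
                    ),
                    issue_id=obj["issue_id"],
                    cls=ClassLabel(obj["class"]),
                    policy=obj["policy"],
                    options=tuple(OptionLabel(o) for o in obj["options"]),
                    resolved_option=OptionLabel(obj["resolved_option"]),
                )
            )
    return out
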