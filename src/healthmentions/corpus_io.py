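"""Reading and writing the on-disk artifacts of the pipeline.

Tweets travel as JSON-lines (one object per line, mirroring the shape of a
Twitter API export), annotations as UTF-8 CSV with a header row, and keyword
lexicons as a JSON mapping of issue name to a list of keyword phrases.
Only the fields named on :class:`TweetRecord` are required in tweet JSONL;
extra keys are ignored on read and not written back.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TweetRecord",
    "HealthIssueLexicon",
    "AnnotationRecord",
    "read_tweets",
    "write_tweets",
    "read_annotations",
    "write_annotations",
    "read_lexicon",
    "write_lexicon",
    "default_lexicon",
]


@dataclass(frozen=True)
class TweetRecord:
    """One short social-media post plus the metadata the filter needs.

    ``has_coordinates`` / ``has_place`` record only the *presence* of
    geolocation fields; the upstream collection pipeline decides what they
    contain.  ``lang`` is a BCP-47-style code or empty when unknown.
    """

    id: str
    text: str
    lang: str = ""
    has_coordinates: bool = False
    has_place: bool = False
    place_country: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("TweetRecord.id must be non-empty")
        if self.text is None:  # pragma: no cover - defensive
            raise ValueError("TweetRecord.text must not be None")


@dataclass(frozen=True)
class HealthIssueLexicon:
    """Keyword phrases (1-3 lowercase words each) for one health issue."""

    issue_id: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.issue_id:
            raise ValueError("issue_id must be non-empty")
        if not self.terms:
            raise ValueError(f"lexicon for {self.issue_id!r} has no terms")
        lowered = tuple(t.lower() for t in self.terms)
        if len(set(lowered)) != len(lowered):
            raise ValueError(
                f"duplicate phrases in lexicon for {self.issue_id!r}"
            )
        object.__setattr__(self, "terms", lowered)


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotator's option choice for one tweet."""

    tweet_id: str
    annotator_id: str
    option: str  # validated against the taxonomy in :mod:`annotation`


# ---------------------------------------------------------------------------
# tweets: JSON-lines

_TWEET_FIELDS = (
    "id",
    "text",
    "lang",
    "has_coordinates",
    "has_place",
    "place_country",
)


def read_tweets(path: str | Path) -> list[TweetRecord]:
    """Read tweet records from a JSONL file, in file order.

    Lines that are not valid JSON objects or lack ``id``/``text`` are
    skipped; the number of skipped lines is logged as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[TweetRecord] = []
    skipped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise ValueError("line is not a JSON object")
                rec = TweetRecord(
                    id=str(obj["id"]),
                    text=obj["text"],
                    lang=obj.get("lang", "") or "",
                    has_coordinates=bool(obj.get("has_coordinates", False)),
                    has_place=bool(obj.get("has_place", False)),
                    place_country=obj.get("place_country", "") or "",
                )
            except (KeyError, ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping line %d of %s: %s", lineno, path, exc)
                continue
            records.append(rec)
    if skipped:
        logger.warning("skipped %d unparseable line(s) in %s", skipped, path)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate tweet ids in {path}")
    return records


def write_tweets(records: Iterable[TweetRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# annotations: CSV with header tweet_id,annotator_id,option


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[AnnotationRecord] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"tweet_id", "annotator_id", "option"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path} must have header columns tweet_id,annotator_id,option"
            )
        for row in reader:
            out.append(
                AnnotationRecord(
                    tweet_id=row["tweet_id"],
                    annotator_id=row["annotator_id"],
                    option=row["option"],
                )
            )
    return out


def write_annotations(
    records: Iterable[AnnotationRecord], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tweet_id", "annotator_id", "option"])
        for rec in records:
            writer.writerow([rec.tweet_id, rec.annotator_id, rec.option])


# ---------------------------------------------------------------------------
# lexicon: JSON mapping issue_id -> [terms]


def read_lexicon(path: str | Path) -> list[HealthIssueLexicon]:
    """Read a keyword lexicon from a JSON mapping issue_id -> [phrases].

    Phrases are lower-cased on read.  Duplicate phrases within an issue and
    duplicate issue names are fatal, as is an empty phrase list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(encoding="utf-8") as fh:
        data = json.load(fh)
    return _lexicon_from_mapping(data, source=str(path))


def _lexicon_from_mapping(
    data: dict, source: str = "<mapping>"
) -> list[HealthIssueLexicon]:
    if not isinstance(data, dict):
        raise ValueError(f"{source}: lexicon must be a JSON object")
    seen: set[str] = set()
    out: list[HealthIssueLexicon] = []
    for issue_id, terms in data.items():
        if issue_id in seen:  # dict keys are unique; keep guard for callers
            raise ValueError(f"{source}: duplicate issue_id {issue_id!r}")
        seen.add(issue_id)
        out.append(HealthIssueLexicon(issue_id=issue_id, terms=tuple(terms)))
    return out


def write_lexicon(
    lexicons: Sequence[HealthIssueLexicon], path: str | Path
) -> None:
    data = {lx.issue_id: list(lx.terms) for lx in lexicons}
    if len(data) != len(lexicons):
        raise ValueError("duplicate issue_id in lexicon set")
    Path(path).write_text(
        json.dumps(data, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def default_lexicon() -> list[HealthIssueLexicon]:
    """The package's shipped 34-issue keyword lexicon.

    A reconstruction from the canonical issue names (each name plus obvious
    inflections), suitable for demonstrations and synthetic corpora; it is
    not a clinically curated keyword list.
    """
    ref = resources.files("healthmentions.data").joinpath(
        "default_lexicon.json"
    )
    data = json.loads(ref.read_text(encoding="utf-8"))
    return _lexicon_from_mapping(data, source="default_lexicon.json")
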