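"""Four-family feature extraction for health-mention classification.

Each post is reduced to a multiset of feature tokens (a ``FeatureBag``,
stored as :class:`collections.Counter`) drawn from four families:

1. **Lexical** — lower-cased lemmas of nouns, verbs and pronouns.  Pronouns
   are deliberately kept although they are classic stop words: first- and
   third-person pronouns are among the strongest cues that a post is about
   a specific person's health.
2. **Dependency** — one token ``relation_governor_dependent`` per
   dependency arc that touches a health-issue keyword.  Before parsing,
   every matched issue term (from the *union* of all lexicon terms) is
   replaced by the placeholder ``diagnosis`` so that, e.g., "I have cancer"
   and "I have lupus" yield the same ``dobj_have_diagnosis`` feature and
   the feature space is shared across issues.
3. **Punctuation & emoji** — each punctuation character and emoji code
   point, counted per occurrence.
4. **Entity markers** — ``HTTP_LINK`` / ``HASHTAG`` / ``AT_USER``
   existence flags, count exactly 1 when present.  URLs and @handles are
   stripped before parsing; a hashtag's word body is kept as text.

Extraction is a pure function of (text, issue terms, backend version).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from typing import Iterable

from .parsing import ParserBackend, RuleBasedBackend, is_emoji

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureBag",
    "MARKER_HTTP_LINK",
    "MARKER_HASHTAG",
    "MARKER_AT_USER",
    "DIAGNOSIS_TOKEN",
    "normalize_entities",
    "merge_issue_terms",
    "lexical_features",
    "dependency_features",
    "punct_emoji_features",
    "extract",
]

FeatureBag = Counter  # feature token -> positive count

MARKER_HTTP_LINK = "HTTP_LINK"
MARKER_HASHTAG = "HASHTAG"
MARKER_AT_USER = "AT_USER"
DIAGNOSIS_TOKEN = "diagnosis"

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_AT_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#(\w+)")
_WS_RE = re.compile(r"\s+")


def normalize_entities(text: str) -> tuple[str, set[str]]:
    """Detect URLs, #hashtags and @handles; return cleaned text + markers.

    Markers are existence features: one per family no matter how many
    occurrences.  URL and handle strings are removed from the text handed
    to the parser; the hashtag keeps its word body.
    """
    markers: set[str] = set()
    if _URL_RE.search(text):
        markers.add(MARKER_HTTP_LINK)
        text = _URL_RE.sub(" ", text)
    if _AT_RE.search(text):
        markers.add(MARKER_AT_USER)
        text = _AT_RE.sub(" ", text)
    if _HASHTAG_RE.search(text):
        markers.add(MARKER_HASHTAG)
        text = _HASHTAG_RE.sub(r"\1", text)
    return _WS_RE.sub(" ", text).strip(), markers


def _term_pattern(terms: Iterable[str]) -> re.Pattern:
    # longest phrase first so "heart attack" wins over "heart"
    ordered = sorted({t.lower() for t in terms}, key=len, reverse=True)
    alts = "|".join(re.escape(t).replace(r"\ ", r"\s+") for t in ordered)
    return re.compile(rf"(?<!\w)(?:{alts})(?!\w)", re.IGNORECASE)


def merge_issue_terms(text: str, issue_terms: Iterable[str]) -> str:
    """Replace every whole-word/phrase issue-term match with ``diagnosis``."""
    terms = list(issue_terms)
    if not terms:
        return text
    return _term_pattern(terms).sub(DIAGNOSIS_TOKEN, text)


_LEXICAL_POS = {"NOUN", "VERB", "PRON", "PROPN"}


def lexical_features(
    text: str, backend: ParserBackend | None = None
) -> Counter:
    """Lower-cased lemmas of noun/verb/pronoun tokens, per occurrence."""
    backend = backend or RuleBasedBackend()
    tokens, _ = backend.parse(text)
    return Counter(
        t.lemma.lower() for t in tokens if t.pos in _LEXICAL_POS
    )


def dependency_features(
    text: str,
    issue_terms: Iterable[str],
    backend: ParserBackend | None = None,
) -> Counter:
    """``relation_governor_dependent`` tokens for arcs touching an issue term.

    Issue phrases are first collapsed to the single token ``diagnosis``;
    only arcs whose governor or dependent is that token are emitted.  A
    parser failure yields an empty set with a warning (the post still gets
    its other feature families).
    """
    backend = backend or RuleBasedBackend()
    merged = merge_issue_terms(text, issue_terms)
    try:
        _, arcs = backend.parse(merged)
    except Exception as exc:  # pragma: no cover - backend-dependent
        logger.warning("dependency parse failed (%s); skipping family", exc)
        return Counter()
    out: Counter = Counter()
    for arc in arcs:
        gov = arc.head.lemma.lower()
        dep = arc.dep.lemma.lower()
        if DIAGNOSIS_TOKEN in (gov, dep):
            out[f"{arc.relation}_{gov}_{dep}"] += 1
    return out


def punct_emoji_features(text: str) -> Counter:
    """Each punctuation character and emoji code point, per occurrence."""
    out: Counter = Counter()
    for ch in text:
        if is_emoji(ch):
            out[ch] += 1
        elif not ch.isspace() and _is_punct(ch):
            out[ch] += 1
    return out


def _is_punct(ch: str) -> bool:
    import unicodedata

    return unicodedata.category(ch).startswith("P")


def extract(
    text: str,
    issue_terms: Iterable[str],
    backend: ParserBackend | None = None,
) -> Counter:
    """Union of the four feature families for one post."""
    backend = backend or RuleBasedBackend()
    cleaned, markers = normalize_entities(text)
    bag: Counter = Counter()
    bag.update(lexical_features(cleaned, backend))
    bag.update(dependency_features(cleaned, issue_terms, backend))
    bag.update(punct_emoji_features(cleaned))
    for m in markers:
        bag[m] = 1
    # invariant: no zero or negative counts stored
    return +bag
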