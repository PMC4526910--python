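"""Stream filtering: language/geolocation predicate + keyword binning.

The collection stage keeps posts written in one language and (optionally)
carrying geolocation evidence, then routes each surviving post into one
bin per health issue whose keyword lexicon it matches.  Matching is
case-insensitive whole-word/whole-phrase matching with word boundaries on
both ends, so ``#cancer`` and ``cancer's`` match ``cancer`` but
``cancerous`` does not.  A post matching several issues is duplicated into
every matching bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import HealthIssueLexicon, TweetRecord
from .features import _term_pattern

__all__ = ["FilterReport", "passes_stream_filter", "match_issues", "bin_stream"]


@dataclass
class FilterReport:
    """Counts describing one binning run."""

    n_read: int
    n_pass_predicate: int
    n_retained: int  # distinct tweets placed in >= 1 bin
    bin_counts: dict[str, int]

    @property
    def retention_pct(self) -> float:
        """Distinct retained / read, as a percentage rounded to 2 decimals."""
        if self.n_read == 0:
            return 0.0
        return round(100.0 * self.n_retained / self.n_read, 2)


def passes_stream_filter(
    tweet: TweetRecord, require_geo: bool = True, allowed_lang: str = "en"
) -> bool:
    """Language + geolocation predicate (total function).

    True iff the post's language matches ``allowed_lang`` and, when
    ``require_geo``, it carries coordinates or a place field.  The
    geolocation test is presence-of-fields, not polygon containment.
    """
    if tweet.lang != allowed_lang:
        return False
    if require_geo and not (tweet.has_coordinates or tweet.has_place):
        return False
    return True


def match_issues(
    text: str, lexicons: Sequence[HealthIssueLexicon]
) -> set[str]:
    """Issue ids with at least one whole-word/phrase keyword match."""
    if not lexicons:
        raise ValueError("lexicon set must be non-empty")
    out: set[str] = set()
    for lx in lexicons:
        if _term_pattern(lx.terms).search(text):
            out.add(lx.issue_id)
    return out


def bin_stream(
    tweets: Iterable[TweetRecord],
    lexicons: Sequence[HealthIssueLexicon],
    require_geo: bool = True,
    allowed_lang: str = "en",
) -> tuple[dict[str, list[TweetRecord]], FilterReport]:
    """Route posts through the predicate and into per-issue keyword bins.

    Returns the bins (one ordered list per issue, every issue present even
    if empty) and a :class:`FilterReport`.  A post matching *k* issues
    appears in all *k* bins but counts once toward retention.
    """
    bins: dict[str, list[TweetRecord]] = {lx.issue_id: [] for lx in lexicons}
    patterns = {lx.issue_id: _term_pattern(lx.terms) for lx in lexicons}
    n_read = n_pass = n_retained = 0
    for tweet in tweets:
        n_read += 1
        if not passes_stream_filter(tweet, require_geo, allowed_lang):
            continue
        n_pass += 1
        hit = False
        for issue_id, pat in patterns.items():
            if pat.search(tweet.text):
                bins[issue_id].append(tweet)
                hit = True
        if hit:
            n_retained += 1
    report = FilterReport(
        n_read=n_read,
        n_pass_predicate=n_pass,
        n_retained=n_retained,
        bin_counts={k: len(v) for k, v in bins.items()},
    )
    return bins, report
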