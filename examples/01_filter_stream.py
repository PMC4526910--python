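"""Keyword-filter a small post stream into per-issue bins.

Posts must be in English and carry geolocation evidence; each surviving
post lands in every issue bin whose keywords it matches.
"""

from healthmentions import TweetRecord, bin_stream, default_lexicon

stream = [
    TweetRecord("t1", "my little cousin has leukemia", "en", True, False),
    TweetRecord("t2", "cancer ward visit then the leukemia drive", "en", False, True),
    TweetRecord("t3", "J'ai la grippe", "fr", True, False),          # wrong language
    TweetRecord("t4", "I think I have the flu", "en", False, False),  # no geolocation
    TweetRecord("t5", "nothing medical here", "en", True, False),     # no keyword
]

bins, report = bin_stream(stream, default_lexicon(), require_geo=True, allowed_lang="en")

print(f"read {report.n_read} posts; {report.n_pass_predicate} passed the "
      f"language/geo predicate; {report.n_retained} matched a keyword "
      f"({report.retention_pct}% retention)")
for issue, members in bins.items():
    if members:
        print(f"  bin {issue!r}: {[t.id for t in members]}")

# t2 appears in both the cancer and leukemia bins but counts once toward
# retention; t3 and t4 fail the stream predicate before keyword matching.
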