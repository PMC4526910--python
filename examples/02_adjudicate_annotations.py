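"""Resolve dual-annotator labels into the four dataset variants.

Each post gets two 7-option annotations (author / relative_or_friend /
someone_else are the positive, personal-mention class; metaphor /
viewpoint / worry / na are negative).  The four policies differ only on
posts whose two mapped classes conflict.
"""

from healthmentions import OptionLabel, TweetRecord, build_dataset
from healthmentions.annotation import agreement_rate

tweets = {
    "t1": TweetRecord("t1", "I'm suffering from schizophrenia"),
    "t2": TweetRecord("t2", "didn't she have a miscarriage?"),
    "t3": TweetRecord("t3", "that exam gave me a heart attack"),
}
annos = {
    "t1": [OptionLabel.AUTHOR, OptionLabel.AUTHOR],                    # agree: positive
    "t2": [OptionLabel.SOMEONE_ELSE, OptionLabel.RELATIVE_OR_FRIEND],  # agree at class level
    "t3": [OptionLabel.METAPHOR, OptionLabel.SOMEONE_ELSE,             # conflict ...
           OptionLabel.VIEWPOINT],                                     # ... tiebreaker says negative
}

print(f"class-level agreement: {agreement_rate(annos):.2f}")
for policy in ("gold", "cap", "can", "tiebreak"):
    ds = build_dataset(tweets, annos, policy)
    summary = {lt.tweet.id: lt.cls.value for lt in ds}
    print(f"{policy:>8}: {summary}")

# gold drops the conflicted t3; CAP calls it positive, CAN negative, and
# tiebreak follows the 2-of-3 majority of the mapped classes (negative).
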