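"""Turn posts into feature bags: lemmas, dependency triples, punctuation
and emoji, and link/hashtag/handle markers.

Any matched health-issue term is collapsed to the placeholder "diagnosis"
inside dependency features, so "I have cancer" and "I have lupus" share
the dobj_have_diagnosis feature across issues.
"""

from healthmentions import extract

issue_terms = ["cancer", "leukemia", "lupus", "heart attack"]

for text in (
    "I have cancer",
    "my uncle is cancer free !!!!!! lol",
    "prayers for my dad, he is fighting leukemia \U0001f622 http://pic.x/1",
):
    bag = extract(text, issue_terms)
    print(f"{text!r}\n  -> {dict(sorted(bag.items()))}")

# Note the existence markers (HTTP_LINK) always count 1, punctuation
# counts per occurrence, and pronouns like "my" are kept on purpose:
# they are among the strongest cues of a personal health mention.
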