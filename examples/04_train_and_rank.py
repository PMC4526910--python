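"""Train the naive Bayes mention classifier on a synthetic corpus, score
new posts, and inspect its most informative features.
"""

from healthmentions import (
    CorpusSpec,
    IssueSpec,
    datasets_from_corpus,
    extract,
    generate,
    rank_features,
    score,
    train,
)

spec = CorpusSpec(
    issues=(IssueSpec("cancer", 600, 0.30, 0.20, 0.50,
                      signal_strength=0.9, disagreement_rate=0.1),),
    seed=7,
)
dataset = datasets_from_corpus(generate(spec), "gold")["cancer"]
terms = ["cancer"]
bags = [(extract(lt.tweet.text, terms), lt.cls) for lt in dataset]
model = train(bags, alpha=1.0)

print(f"trained on {len(bags)} posts, vocabulary {len(model.vocab)}")
print("top-10 positive-class features:", rank_features(model, 10))
for text in ("I have cancer", "more cancer research funding is needed"):
    p = score(model, extract(text, terms))
    print(f"P(personal mention | {text!r}) = {p:.3f}")

# The top features recover the planted cues: first-person pronouns,
# have/battle verbs and the shared dobj_have_diagnosis dependency.
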