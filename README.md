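# healthmentions

Detecting **personal health status mentions** in short social-media posts.

A post is a *positive* mention when it discloses the health condition of a
specific, potentially identifiable person — the author ("I'm suffering from
schizophrenia and a little bit of insomnia") or someone else ("my little
cousin has leukemia"). The same health-issue keywords also appear in
metaphors ("you're gonna give Viv a heart attack"), general viewpoints, and
worries, which are all *negative*. Telling these apart at stream scale, for
many health issues at once, is the problem this package addresses. It is
aimed at infodemiology and consumer-health researchers who want to filter a
post stream down to genuine disclosures and study who discloses what.

## What's inside

The pipeline, end to end, with every stage importable on its own:

- **`filtering`** — language/geolocation predicate and case-insensitive
  whole-phrase keyword matching that routes posts into per-issue bins. A
  reconstructed 34-issue keyword lexicon ships with the package.
- **`annotation`** — the 7-option label taxonomy (author,
  relative_or_friend, someone_else | metaphor, viewpoint, worry, na), its
  binary projection, and four adjudication policies for dual-annotated
  posts: **gold** (drop conflicts), **CAP** (conflict→positive), **CAN**
  (conflict→negative), **TieBreak** (third-annotator majority).
- **`features`** — four feature families per post: lemmas of
  nouns/verbs/pronouns (pronouns deliberately kept), dependency triples
  anchored on health-issue terms with the term collapsed to a shared
  `diagnosis` placeholder (so `dobj_have_diagnosis` transfers across
  issues), punctuation/emoji counts, and link/hashtag/handle existence
  markers. Parsing is done by a pinned, deterministic rule-based backend
  behind a pluggable interface.
- **`classifier`** — multinomial naive Bayes written out in full:
  P(c) = N_c/N, P(f|c) = (n_cf + α)/(n_c + α|V|), log-space posterior
  scoring, and log-likelihood-ratio feature ranking.
- **`evaluation`** — tie-aware average precision (AUPRC; a constant scorer
  scores exactly the positive prevalence), precision at fixed recall,
  repeated stratified 80/20 splits, and the four cross-issue experiment
  modes **HOC-1/HOC-N** (train and test on the same issue set) and
  **HEC-1/HEC-N** (train and test on disjoint issues).
- **`disclosure`** — per-issue author/others/negative profiles, a
  chi-square test of disclosure rate vs issue (df = k−1), and a Spearman
  rank test of author rate vs others rate reported as Z = ρ·√(n−1).
- **`synth`** — a seeded generator of annotated corpora with exact class
  allocation, planted class-indicative tokens of tunable strength, and a
  controllable annotator disagreement rate, so the whole pipeline is
  testable without any external data.

## Worked example

Train on a synthetic single-issue corpus and inspect the model
(`examples/04_train_and_rank.py`):

```text
trained on 537 posts, vocabulary 92
top-10 positive-class features: ['!', 'i', 'my', 'dobj_have_diagnosis', 'have',
 'she', ',', 'diagnose', 'get', 'prep_with_diagnose_diagnosis']
P(personal mention | 'I have cancer') = 1.000
P(personal mention | 'more cancer research funding is needed') = 0.000
```

The most informative features are first-person pronouns, have/get verbs and
the shared `dobj_have_diagnosis` dependency — exactly the cues the
generator plants in positive posts, and the classic signature of personal
health mentions. The posterior is the probability that a new post is a
genuine disclosure.

Each script in `examples/` demonstrates one capability the same way:
filtering, adjudication, feature extraction, training, cross-issue
evaluation, disclosure analysis. A thin CLI (`healthmentions <stage>`)
exposes the same stages for shell pipelines; see `healthmentions --help`.

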