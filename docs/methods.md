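# Methods

This note documents the models, conventions and design choices behind
`healthmentions`: what each stage computes, the parameters that matter,
what the synthetic corpora do and do not emulate, and the numerical
details a user reproducing or extending the analyses should know.

## Problem setting

A *personal health mention* is a statement disclosing the health condition
of a specific, potentially identifiable person. Detection is binary
classification over short posts: positive when the post discloses the
author's or another specific person's status, negative when the
health-issue term is used metaphorically, as general commentary, as worry,
or in spam. The pipeline mirrors a stream-processing deployment: keyword
filtering into per-issue bins, crowd annotation and adjudication, feature
extraction, a generative classifier, and ranked (threshold-free)
evaluation.

## Filtering

The stream predicate keeps posts whose language code equals the configured
one (default `en`) and, when geolocation is required, that carry either
coordinates or a place field. Geolocation is a *presence* test, not
polygon containment of a geographic region: the package has no boundary
geometry, and presence-of-geo already excludes the organizational accounts
that typically omit it.

Keyword matching is case-insensitive whole-word/whole-phrase matching with
word boundaries on both ends (`\w`-based), so `#cancer` and `cancer's`
match `cancer` while `cancerous` does not; multi-word phrases match across
whitespace. A post matching k issues is duplicated into all k bins — bins
are per-issue samples, and duplication keeps each issue's sample complete —
but counts once toward the retention fraction (distinct retained / read,
reported as a percentage rounded to 2 decimals). The predicate is applied
before keyword matching; the composition is commutative, so the order is
an implementation convenience.

The shipped 34-issue lexicon is a reconstruction from canonical issue
names plus obvious inflections ("migraine"/"migraines"). It is **not** a
clinically curated keyword list; substitute your own JSON
(`issue_id -> [phrases]`) for real studies.

## Annotation and adjudication

Seven options describe how a post uses a health-issue term; they project
onto the binary class as author/relative_or_friend/someone_else → positive
and metaphor/viewpoint/worry/na → negative. Two primary annotators label
each post; the four dataset policies handle class-level conflicts:

| policy | agreeing pair | conflicting pair |
|---|---|---|
| gold | mapped class | dropped |
| CAP | mapped class | positive |
| CAN | mapped class | negative |
| TieBreak | mapped class | majority of 3 mapped classes |

TieBreak's majority vote operates on *mapped classes*, not raw options:
the decision of record is binary, three binary votes always produce a
majority, and this sidesteps the undefined case of a third annotator
introducing a brand-new option. Inter-annotator agreement is class-level
percent agreement over the two primary annotators.

Every labeled post carries a `resolved_option` for the disclosure
analysis: the first contributing annotator whose mapped class equals the
adjudicated class. When CAP/CAN overrides a conflict and *no* annotator
sits on the winning side (impossible for a 2-annotator conflict, possible
in principle for degenerate inputs), a canonical option of the winning
class is used.

## Feature extraction

Four families, unioned into one multiset per post:

1. **Lexical**: lower-cased lemmas of tokens tagged noun, verb or pronoun,
   counted per occurrence. Pronouns are kept deliberately: first- and
   third-person pronouns are primary cues of a personal mention.
2. **Dependency**: `relation_governor_dependent` strings for every arc
   touching a health-issue term, with all matched terms (the union of the
   whole lexicon, not only the post's bin issue) collapsed to the single
   token `diagnosis` before parsing. Collapsing compacts the feature space
   and is what lets a classifier trained on some issues transfer to
   others: `dobj_have_diagnosis` is issue-agnostic.
3. **Punctuation and emoji**: each punctuation character (Unicode `P*`
   category) and each emoji code point, counted per occurrence — a
   multinomial reading consistent with the classifier; `!!!` contributes
   count 3.
4. **Entity markers**: `HTTP_LINK`, `HASHTAG`, `AT_USER`, existence-only
   (count exactly 1). URLs and handles are stripped before parsing; a
   hashtag keeps its word body as text.

Extraction is a pure function of (text, issue terms, backend version).

### The parser backend

Tokenization, POS tagging, lemmatization and dependency parsing sit behind
a small protocol; the pinned default is a hand-written rule-based backend
(closed-class word lists, a suffix lemmatizer with an irregular-verb
table, and head-finding heuristics emitting Stanford-style arcs: `nsubj`,
`dobj`, `iobj`, `poss`, `amod`, `compound`, collapsed `prep_*`). It is
deterministic, dependency-free and exact on the constructions that carry
the classification signal ("I have X", "my mom has X", "she is fighting
X"), at the price of shallow coverage of everything else. Dependency
feature strings are therefore backend-specific: swapping in a statistical
parser changes the relation vocabulary (e.g. `dobj` vs `obj`) but not the
extractor contract, and models should not be transferred across backends.

## Classifier

Multinomial naive Bayes with additive smoothing:
P(c) = N_c/N and P(f|c) = (n_cf + α)/(n_c + α|V|), with α = 1 (Laplace) by
default and configurable. Scoring runs in log space and normalizes over
the two classes, so the two posteriors sum to 1 by construction. Features
unseen in training are dropped at scoring time (standard multinomial NB
practice), which keeps train and test vocabularies decoupled in
cross-issue transfer. Feature ranking uses the log-likelihood ratio
log P(f|pos) − log P(f|neg), ties broken lexicographically.

Two smoothing-related subtleties are worth noting. Duplicating every
training document leaves priors unchanged exactly, but shifts the smoothed
conditionals slightly (the pseudo-counts do not double); the invariance
holds in the α→0 limit and is tested there. And with fixed α, larger
corpora are sharper — intended behavior, not a bug.

## Evaluation

**Tie-aware average precision.** Posts are ranked by score descending;
tied scores form one block evaluated atomically, and AUPRC is
Σ_blocks (block_tp/n_pos)·precision-at-block-end. This makes a constant
scorer's AUPRC equal the positive prevalence — the natural chance baseline
under class imbalance — where trapezoidal interpolation across a tie block
would be optimistic. The accumulation is done in exact rational arithmetic
and rounded once at the end, so the algebraic laws (perfect ranking → 1,
all-tied → prevalence) hold exactly in the returned float. Precision at
recall r is read off the step curve at the first point with recall ≥ r.

**Splits and replicates.** Stratified splits shuffle each class with a
replicate-specific seed (`seed + rep`) and send ⌊train_frac·n_c⌋ posts to
train. Every experiment runs 30 replicates by default and reports the mean
and sample SD of AUPRC.

**Experiment modes.** HOC (homogeneous) trains and tests on the same issue
set via the 80/20 split; HEC (heterogeneous) trains on the 80% side of the
training issues and scores the *entire* labeled set of the disjoint test
issues — since no post can leak across, holding test data out would only
lose power. Train/test issue overlap in HEC is a hard error. An optional
training budget stratified-subsamples the training side so classifiers
compared at equal training size are genuinely equal; subsampling uses
largest-remainder allocation across classes. Using the split's train side
in HEC is also what gives HEC replicates their variance; with the full
training pool every replicate would be identical.

## Disclosure statistics

The per-issue profile counts author, others (relative_or_friend +
someone_else) and negative posts; author rate + others rate = positive
rate. Two planned tests, no multiplicity adjustment:

- **Chi-square**: Pearson Σ(O−E)²/E on the 2×k positive/negative table
  with expected counts from the margins, df = k−1 (each issue's total is
  fixed at the sampling design, e.g. 100 posts per issue), p from the χ²
  survival function. A zero expected count is a hard error naming the
  cell.
- **Spearman**: ρ is the Pearson correlation of mid-ranks of the author-
  and others-rate vectors; the statistic is reported as Z = ρ·√(n−1) with
  a two-sided normal p-value. This is one of several asymptotic
  conventions (the t approximation is the common alternative); it is the
  one used because the result of record is a Z statistic.

Both are implemented directly (the ranks, the expected counts, the sums)
with scipy used only for the χ² and normal distribution functions; the
test suite cross-checks both against `scipy.stats` on random tables.

## Synthetic corpora

The generator emulates the *statistical* structure the pipeline assumes,
not language. Per issue it takes n_tweets, option-class probabilities
(p_author, p_others, p_negative), a signal strength s, and an annotator
disagreement rate d.

- **Exact allocation** (default): class counts come from largest-remainder
  rounding — positives vs negatives first, then options within each class
  — followed by a seeded shuffle, so a fixture mirroring a printed class
  table reproduces its counts verbatim. The default four-issue
  gold-standard specs use positive/negative counts 166/697 (cancer),
  261/461 (depression), 211/551 (hypertension), 436/423 (leukemia), with
  cancer/leukemia skewed toward others-disclosure and
  depression/hypertension toward author-disclosure.
- **Templates**: each post fills a class-appropriate ASCII template
  embedding the issue term (author: first person + have/suffer; others:
  kin terms + third person; negatives: metaphor/viewpoint/worry/spam
  phrasings), plus 1–3 noise tokens from a shared vocabulary. With
  probability 1−s a class-neutral template is used instead, so s
  interpolates from no signal (s=0) to perfect separability (s=1). The
  planted positive indicators are the pronouns "i" and "my"; "hope",
  "lol" and "should" mark negatives. Default s = 0.9 — strong but not
  deterministic signal; the learning-curve analyses use s = 0.65, where
  the classifier is off-ceiling and training-set size still matters.
- **Annotators**: A1 reports the true option; A2 flips the mapped class
  with probability d (default 0.1, giving ~90% class-level agreement —
  the high-concordance regime of vetted annotators) and then picks a
  uniform option within the flipped class; A3, the tiebreaker, reports
  the truth. At d = 0 all four adjudication policies coincide.

What passing tests on this corpus shows: the pipeline's mechanics —
adjudication algebra, feature extraction, estimation, ranking, transfer of
shared features — are correct, and the classifier recovers planted
structure. What it does not show: performance on real posts, whose
misspellings, sarcasm, code-switching and topic drift the templates do not
model. Real-data AUPRCs will be substantially lower than the synthetic
ones.

## The acceptance script

`scripts/acceptance.py --seed S --out f.json` regenerates everything from
scratch at desk scale: a 34-issue survey corpus (100 posts per issue,
d = 0.1) whose author/others profiles follow the published per-issue
disclosure figures where printed and otherwise spread author- and
others-skewed profiles across the published 9%–88% positive-rate range;
and the four-issue gold-standard corpus above. It reports filter
retention, annotator agreement, the TieBreak positive rate, χ² (df 33) and
Spearman Z across the 34 issues, HOC-N AUPRC (mean/SD over 30 replicates),
HEC-N transfer AUPRC to the 30 unseen issues' TieBreak datasets, and
precision at recall 0.4 on the transfer curve. Problem sizes (100 posts
per survey issue, ~3 200 training posts) are the package's desk-scale
defaults; every reported number is computed at run time from the seeded
corpora.

## Known limitations

- The rule-based parser's coverage is shallow; dependency features on
  real-world syntax will be noisier than on templates.
- Emoji detection is by code-point range, not a curated emoji inventory;
  rare symbols may be missed or over-included.
- The shipped lexicon is a naming reconstruction, not expert-curated.
- Geolocation filtering is presence-based; no country/region geometry.
- The evaluation harness exports per-replicate AUPRC vectors but does not
  run significance tests between classifiers; users can apply any paired
  test to the exported vectors.
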