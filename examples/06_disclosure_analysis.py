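"""Per-issue disclosure profiles and the two planned hypothesis tests.

The chi-square test asks whether the positive (disclosure) rate depends
on the health issue; the Spearman test asks whether issues where people
disclose their own status are the same issues where they disclose other
people's.
"""

from healthmentions import (
    CorpusSpec,
    IssueSpec,
    chi_square_disclosure,
    datasets_from_corpus,
    disclosure_profile,
    generate,
    spearman_disclosure,
)

# author-skewed issues on the left, others-skewed on the right
profiles = {
    "insomnia": (0.69, 0.01), "migraine": (0.75, 0.08),
    "bronchitis": (0.80, 0.08), "allergies": (0.74, 0.11),
    "miscarriage": (0.12, 0.40), "leukemia": (0.08, 0.30),
    "alzheimers": (0.05, 0.30), "heart_attack": (0.06, 0.06),
}
issues = tuple(
    IssueSpec(name, 100, a, o, round(1 - a - o, 12), disagreement_rate=0.1)
    for name, (a, o) in profiles.items()
)
labeled = [
    lt
    for ds in datasets_from_corpus(
        generate(CorpusSpec(issues=issues, seed=9)), "tiebreak"
    ).values()
    for lt in ds
]

table = disclosure_profile(labeled)
for issue, row in table.items():
    print(f"{issue:>14}: author {row.author_rate:.2f}  "
          f"others {row.others_rate:.2f}  positive {row.positive_rate:.2f}")

chi2, df, p = chi_square_disclosure(table)
print(f"\ndisclosure rate vs issue: chi2({df}) = {chi2:.1f}, p = {p:.2e}")
rho, z, p = spearman_disclosure(table)
print(f"author rate vs others rate: rho = {rho:.2f}, Z = {z:.2f}, p = {p:.3f}")

# A large chi-square rejects issue-independent disclosure; a negative Z
# says author-heavy issues tend not to be others-heavy.
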