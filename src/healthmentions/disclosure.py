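"""Per-issue disclosure profiles and the two planned hypothesis tests.

For each health issue the profile splits its labeled posts into
*author* (the poster's own status), *others* (a relative, friend, or other
specific person) and *negative* (metaphor, viewpoint, worry, spam).  The
author and others rates stack to the issue's positive rate.

Two tests probe whether disclosure behavior depends on the issue:

* **Chi-square** on the 2 x k table of positive/negative counts per issue
  (Pearson ``sum((O-E)^2 / E)``; with each issue's total fixed by the
  sampling design, df = k - 1).
* **Spearman rank correlation** between the per-issue author rate and
  others rate, using mid-ranks for ties; reported as
  ``Z = rho * sqrt(n - 1)`` with a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .annotation import ClassLabel, LabeledTweet, OptionLabel

__all__ = [
    "DisclosureRow",
    "DisclosureTable",
    "disclosure_profile",
    "chi_square_disclosure",
    "spearman_disclosure",
]


@dataclass(frozen=True)
class DisclosureRow:
    n_author: int
    n_others: int
    n_negative: int

    def __post_init__(self) -> None:
        if min(self.n_author, self.n_others, self.n_negative) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_author + self.n_others + self.n_negative

    @property
    def author_rate(self) -> float:
        return self.n_author / self.n_total

    @property
    def others_rate(self) -> float:
        return self.n_others / self.n_total

    @property
    def positive_rate(self) -> float:
        return (self.n_author + self.n_others) / self.n_total


DisclosureTable = dict[str, DisclosureRow]

_OTHERS = {OptionLabel.RELATIVE_OR_FRIEND, OptionLabel.SOMEONE_ELSE}


def disclosure_profile(labeled: Sequence[LabeledTweet]) -> DisclosureTable:
    """Count author / others / negative posts per issue."""
    counts: dict[str, list[int]] = {}
    for lt in labeled:
        row = counts.setdefault(lt.issue_id, [0, 0, 0])
        if lt.cls is ClassLabel.NEGATIVE:
            row[2] += 1
        elif lt.resolved_option is OptionLabel.AUTHOR:
            row[0] += 1
        elif lt.resolved_option in _OTHERS:
            row[1] += 1
        else:  # positive class but option not resolved to a person
            raise ValueError(
                f"positive post {lt.tweet.id!r} lacks a person-level option"
            )
    return {
        issue: DisclosureRow(*row) for issue, row in sorted(counts.items())
    }


def chi_square_disclosure(
    table: DisclosureTable,
) -> tuple[float, int, float]:
    """Pearson chi-square of positive/negative counts across issues.

    Returns ``(chi2, df, p)`` with ``df = k - 1`` for *k* issues (each
    issue's total is fixed by the sampling design).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 issues")
    issues = sorted(table)
    obs = np.array(
        [
            [table[i].n_author + table[i].n_others for i in issues],
            [table[i].n_negative for i in issues],
        ],
        dtype=float,
    )
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    expected = row_tot * col_tot / obs.sum()
    if (expected <= 0).any():
        r, c = np.argwhere(expected <= 0)[0]
        raise ValueError(
            f"expected count is 0 in cell (row {int(r)}, issue {issues[int(c)]!r})"
        )
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(issues) - 1
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties receiving their mid-rank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_disclosure(
    table: DisclosureTable,
) -> tuple[float, float, float]:
    """Spearman correlation of author rate vs others rate across issues.

    Returns ``(rho, z, p)`` with ``z = rho * sqrt(n - 1)`` and a
    two-sided normal p-value.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 issues")
    issues = sorted(table)
    author = np.array([table[i].author_rate for i in issues])
    others = np.array([table[i].others_rate for i in issues])
    if np.ptp(author) == 0 or np.ptp(others) == 0:
        raise ValueError("a rate vector has zero variance")
    ra, ro = _midranks(author), _midranks(others)
    ra = ra - ra.mean()
    ro = ro - ro.mean()
    rho = float(
        (ra * ro).sum() / np.sqrt((ra**2).sum() * (ro**2).sum())
    )
    z = rho * np.sqrt(len(issues) - 1)
    p = float(2 * norm.sf(abs(z)))
    return rho, float(z), p
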