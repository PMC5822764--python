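"""Group comparisons: one-way ANOVA with Bonferroni post hoc, chi-square.

Matches the conventional clinical-paper analysis: classical
(equal-variance) one-way ANOVA for the omnibus test, pooled-variance
two-sample t tests for the pairwise comparisons with a Bonferroni
multiplier equal to the number of pairs, and Pearson's chi-square
(no continuity correction) for categorical demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairwiseT",
    "GroupComparisonResult",
    "ChiSquareResult",
    "anova_bonferroni",
    "chi_square",
]


@dataclass(frozen=True)
class PairwiseT:
    t: float
    raw_p: float
    adj_p: float


@dataclass
class GroupComparisonResult:
    """One-way ANOVA result with Bonferroni-adjusted pairwise tests."""

    parameter: str
    region: str
    groups: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    f: float
    p: float
    pairwise: dict[tuple[str, str], PairwiseT] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return np.isfinite(self.f)

    def stars(self, pair: tuple[str, str]) -> str:
        """Significance stars for a pair (vs-control convention)."""
        p = self.pairwise[pair].adj_p
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""


def anova_bonferroni(
    values_by_group: Mapping[str, Sequence[float]],
    parameter: str = "",
    region: str = "",
) -> GroupComparisonResult:
    """Classical one-way ANOVA plus Bonferroni-adjusted pairwise t tests.

    Pairwise tests use the two-sample pooled-variance t statistic; each
    raw p is multiplied by the number of pairwise comparisons and capped
    at 1.  Degenerate input (zero within-group variance everywhere with
    equal means) yields ``f = nan`` and a ``degenerate`` flag rather than
    an exception.
    """
    groups = tuple(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if a.ndim != 1 or a.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {g!r} contains non-finite values")

    means = {g: float(a.mean()) for g, a in arrays.items()}
    sds = {g: float(a.std(ddof=1)) for g, a in arrays.items()}
    ns = {g: int(a.size) for g, a in arrays.items()}
    flags: list[str] = []

    all_within_zero = all(sd == 0.0 for sd in sds.values())
    if all_within_zero:
        f = p = np.nan
        flags.append("degenerate")
        if len(set(means.values())) > 1:
            flags.append("zero-within-variance-unequal-means")
    else:
        f_res = sps.f_oneway(*arrays.values())
        f, p = float(f_res.statistic), float(f_res.pvalue)

    pairs = list(combinations(groups, 2))
    multiplier = len(pairs)
    pairwise: dict[tuple[str, str], PairwiseT] = {}
    for a, b in pairs:
        if sds[a] == 0.0 and sds[b] == 0.0:
            t = np.inf if means[a] != means[b] else 0.0
            raw = 0.0 if means[a] != means[b] else 1.0
            flags.append(f"degenerate-pair-{a}-{b}")
        else:
            res = sps.ttest_ind(arrays[a], arrays[b], equal_var=True)
            t, raw = float(res.statistic), float(res.pvalue)
        pairwise[(a, b)] = PairwiseT(t=t, raw_p=raw, adj_p=min(1.0, multiplier * raw))

    return GroupComparisonResult(
        parameter=parameter,
        region=region,
        groups=groups,
        means=means,
        sds=sds,
        ns=ns,
        f=f,
        p=p,
        pairwise=pairwise,
        flags=flags,
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    df: int
    expected: np.ndarray


def chi_square(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x k count table.

    No continuity correction is applied (matching the usual demography-
    table convention); any zero row or column marginal is an error since
    the expected counts would vanish.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r x k table with r, k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal: expected counts undefined")
    res = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=int(res.dof),
        expected=res.expected_freq,
    )
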