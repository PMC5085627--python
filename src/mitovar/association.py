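"""Case-control association statistics for haplogroups and mtSNPs.

Association of a binary factor (carriage of a haplogroup label or an mtSNP
allele) with case status is summarized as an odds ratio with a Woolf
(log-normal) 95% confidence interval, plus a Pearson chi-square test
(automatic Fisher's-exact fallback when any expected count drops below 5).
Zero cells get the Haldane-Anscombe +0.5 correction, flagged in the result.
Screens over many factors are reported sorted by p-value; the source design
applies no multiplicity correction, but an optional Benjamini-Hochberg
column is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

ALPHA = 0.05
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ContingencyTable2x2:
    """Counts a,b (cases exposed/unexposed), c,d (controls exposed/unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self):
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    factor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "chi-square"  # chi-square | fisher
    corrected: bool = False  # Haldane-Anscombe applied
    statistic: float | None = None
    p_adjusted: float | None = None


def odds_ratio_ci(table: ContingencyTable2x2, factor: str = "") -> AssociationResult:
    """OR = (a/b)/(c/d) with Woolf 95% CI; +0.5 to all cells on any zero.

    Two zero cells sharing a margin leave the OR undefined -> error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    zero_margin = (a == 0 and b == 0) or (c == 0 and d == 0) or \
                  (a == 0 and c == 0) or (b == 0 and d == 0)
    if zero_margin:
        raise ValueError("odds ratio undefined: empty table margin")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AssociationResult(
        factor=factor,
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - Z_95 * se),
        ci_high=math.exp(math.log(or_) + Z_95 * se),
        p_value=float("nan"),
        corrected=corrected,
    )


def chi_square_test(table: ContingencyTable2x2) -> tuple[float | None, float, str]:
    """Pearson chi-square (df=1, no continuity correction) with Fisher fallback.

    Returns ``(statistic, p, method)``; the statistic is None for Fisher.
    The fallback triggers whenever any expected count is below 5.
    """
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("chi-square undefined: zero table margin")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    # the small-sample boundary is inclusive: an expected count of exactly 5
    # already goes to the exact test
    if expected.min() <= 5:
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        return None, float(p), "fisher"
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p), "chi-square"


def associate(table: ContingencyTable2x2, factor: str = "") -> AssociationResult:
    """Odds ratio + the appropriate test in one result."""
    result = odds_ratio_ci(table, factor=factor)
    stat, p, method = chi_square_test(table)
    result.statistic = stat
    result.p_value = p
    result.method = method
    return result


def screen_factors(
    case_factors: list,
    control_factors: list,
    factors=None,
    adjust: bool = False,
) -> list:
    """One 2x2 association per factor; sorted by p-value.

    ``case_factors``/``control_factors`` are per-individual sets (or
    iterables) of carried factor labels.  Factors carried by nobody are
    skipped.  ``adjust=True`` adds a Benjamini-Hochberg column (the default
    reproduces the source design: no multiplicity correction).
    """
    case_sets = [set(f) for f in case_factors]
    control_sets = [set(f) for f in control_factors]
    if factors is None:
        factors = sorted(set().union(*case_sets, *control_sets, set()))
    results = []
    for factor in factors:
        a = sum(factor in s for s in case_sets)
        c = sum(factor in s for s in control_sets)
        if a + c == 0:
            continue  # carried by nobody: skipped with note
        table = ContingencyTable2x2(a, len(case_sets) - a, c, len(control_sets) - c)
        try:
            results.append(associate(table, factor=factor))
        except ValueError:
            continue  # degenerate margin (e.g. carried by everybody)
    results.sort(key=lambda r: (r.p_value, r.factor))
    if adjust and results:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for r, pa in zip(results, p_adj):
            r.p_adjusted = float(pa)
    return results


def carrier_association(
    carrier_flags, feature_flags, factor: str = ""
) -> AssociationResult:
    """2x2 association of mutation carriage with a binary clinical feature."""
    carrier_flags = list(carrier_flags)
    feature_flags = list(feature_flags)
    if len(carrier_flags) != len(feature_flags):
        raise ValueError("flag vectors must align per individual")
    a = sum(1 for m, f in zip(carrier_flags, feature_flags) if m and f)
    b = sum(1 for m, f in zip(carrier_flags, feature_flags) if m and not f)
    c = sum(1 for m, f in zip(carrier_flags, feature_flags) if not m and f)
    d = sum(1 for m, f in zip(carrier_flags, feature_flags) if not m and not f)
    return associate(ContingencyTable2x2(a, b, c, d), factor=factor)
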