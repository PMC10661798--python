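"""Cohort allele-frequency arithmetic and the 2x2 chi-square test.

Small, exact utilities for the genetics side of a case/cohort study:
the minor allele frequency of a variant in a sequenced cohort, and the
chi-square test of independence on a 2x2 carrier/non-carrier allele table
with the Yates continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ContingencyTable2x2", "allele_frequency", "yates_chi2"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d: rows are cohorts, columns variant vs reference
    alleles.  The test is defined only when every row and column sum is
    positive."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def marginals_positive(self) -> bool:
        return min(self.a + self.b, self.c + self.d,
                   self.a + self.c, self.b + self.d) > 0


def allele_frequency(n_variant_alleles: int, n_individuals: int,
                     ploidy: int = 2) -> float:
    """Allele frequency: variant alleles over total alleles in the cohort.

    For a diploid cohort the denominator is ``2 * n_individuals``; one
    heterozygote among 53 diploid individuals gives 1/106 = 0.0094.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    total = ploidy * n_individuals
    if not 0 <= n_variant_alleles <= total:
        raise ValueError(
            f"n_variant_alleles must be in [0, {total}], got {n_variant_alleles}")
    return n_variant_alleles / total


def yates_chi2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Chi-square test of independence with Yates continuity correction.

    chi2 = N (|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)], clamped to 0
    when the correction overshoots (|ad - bc| <= N/2), with the p-value
    from the chi-square distribution with 1 degree of freedom.
    """
    if not table.marginals_positive():
        raise ValueError("all row and column sums must be positive")
    a, b, c, d = (float(table.a), float(table.b),
                  float(table.c), float(table.d))
    N = a + b + c + d
    diff = abs(a * d - b * c)
    if diff <= N / 2.0:
        return 0.0, 1.0
    chi2 = N * (diff - N / 2.0) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
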