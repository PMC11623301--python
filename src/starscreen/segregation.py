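"""Segregation expectations and exact tests for haploid crosses.

In a haploid cross between a parent carrying n unlinked dominant
resistance loci and a parent carrying none, each locus is inherited with
probability 1/2, so the expected fraction of resistant progeny is
1 - (1-p)^n: 50% for one locus, 75% for two. Observed counts are tested
against such expectations with an exact binomial test, and a marker is
tested for cosegregation with a phenotype with Fisher's exact test on
the 2x2 table; "perfect" segregation means zero off-diagonal counts.

Two-sided p-values use the point-probability method (sum of P(X=i) over
outcomes no more probable than the observed one), the same convention
scipy uses; tests cross-check against direct enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SegTestResult:
    k: int
    n: int
    p0: float
    p_value: float


@dataclass(frozen=True)
class CosegregationResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # [[both, marker only], [pheno only, neither]]
    p_value: float
    perfect: bool


def expected_resistant_fraction(n_loci: int, p: float = 0.5) -> float:
    """P(progeny inherits >= 1 of n unlinked loci), each with probability p."""
    if n_loci < 0:
        raise ValueError("n_loci must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** n_loci


def exact_binomial_test(k: int, n: int, p0: float) -> SegTestResult:
    """Two-sided exact binomial test (point-probability method)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    p = float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    return SegTestResult(k=k, n=n, p0=p0, p_value=min(p, 1.0))


def cosegregation_test(
    marker: Sequence[int] | Sequence[bool], phenotype: Sequence[int] | Sequence[bool]
) -> CosegregationResult:
    """2x2 marker-phenotype contingency with a two-sided Fisher exact test.

    ``perfect`` is True when the off-diagonal cells (marker+/phenotype-
    and marker-/phenotype+) are both zero.
    """
    m = np.asarray(marker, dtype=bool)
    ph = np.asarray(phenotype, dtype=bool)
    if m.shape != ph.shape:
        raise ValueError("marker and phenotype vectors differ in length")
    if m.size < 1:
        raise ValueError("need at least one progeny")
    a = int((m & ph).sum())
    b = int((m & ~ph).sum())
    c = int((~m & ph).sum())
    d = int((~m & ~ph).sum())
    _odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return CosegregationResult(
        table=((a, b), (c, d)),
        p_value=float(min(p, 1.0)),
        perfect=(b == 0 and c == 0),
    )
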