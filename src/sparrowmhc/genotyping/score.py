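"""Multinomial coverage model for amplicon genotype confidence.

An individual carrying ``m`` equally amplified alleles is sequenced to a
total depth of ``T`` reads.  Reads fall on alleles i.i.d. with probability
``1/m`` each.  The *genotyping score* is the probability that every allele
is covered by at least ``t`` reads, i.e. that no allele is missed by the
low-abundance filter.  The per-sample coverage threshold is the smallest
``T`` whose score reaches a requested confidence; for house sparrow MHC
class I (at most eight classical alleles) with ``t = 3`` and 99.9%
confidence this is 104 reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb


@dataclass(frozen=True)
class GenotypingScoreParams:
    """Parameters of the coverage-confidence model.

    m: maximum number of alleles an individual may carry (8 for house
       sparrow classical MHC class I).
    t: minimum reads required per allele (the low-abundance cut-off).
    confidence: required probability that all m alleles are seen >= t times.
    """

    m: int = 8
    t: int = 3
    confidence: float = 0.999

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")


def _covered_sequence_counts(m: int, t: int, tmax: int) -> list[int]:
    """g[T] = number of ordered read-to-allele assignments of length T over
    m labelled alleles in which every allele receives >= t reads.

    Exact integer dynamic programming over alleles; the genotyping score is
    g[T] / m**T.
    """
    g = [1] + [0] * tmax
    for i in range(1, m + 1):
        h = [0] * (tmax + 1)
        for r in range(t * i, tmax + 1):
            h[r] = sum(comb(r, k) * g[r - k] for k in range(t, r - t * (i - 1) + 1))
        g = h
    return g


def genotyping_score(total_reads: int, params: GenotypingScoreParams | None = None,
                     *, m: int | None = None, t: int | None = None) -> float:
    """Probability that all ``m`` equally amplified alleles receive at least
    ``t`` of ``total_reads`` multinomial reads.

    Exact (big-integer) computation; monotone non-decreasing in the total
    read count and non-increasing in ``m`` and ``t``.
    """
    if params is None:
        params = GenotypingScoreParams()
    m = params.m if m is None else m
    t = params.t if t is None else t
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if total_reads < m * t:
        return 0.0
    g = _covered_sequence_counts(m, t, total_reads)
    return float(Fraction(g[total_reads], m ** total_reads))


def min_reads_for_score(params: GenotypingScoreParams | None = None) -> int:
    """Smallest total read count whose genotyping score reaches the
    configured confidence.

    Scans upward from the trivial lower bound ``m * t``, growing the exact
    DP table geometrically.  Guaranteed to terminate: the score tends to 1
    as the total read count grows.
    """
    if params is None:
        params = GenotypingScoreParams()
    m, t, conf = params.m, params.t, params.confidence
    tmax = max(4 * m * t, 64)
    while True:
        g = _covered_sequence_counts(m, t, tmax)
        # exact rational comparison against the confidence
        conf_frac = Fraction(conf)
        for total in range(m * t, tmax + 1):
            if Fraction(g[total], m ** total) >= conf_frac:
                return total
        tmax *= 2
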