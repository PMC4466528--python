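"""Karlin-Altschul statistics for local alignment scores.

Raw scores S are converted to bit scores ``b = (lambda*S - ln K) / ln 2``
and e-values ``E = m * n * 2**(-b)`` over an effective search space of
``m`` database residues times ``n`` query residues, with no edge-length
correction.

For the translated protein search we use the published gapped BLOSUM62
(open 11 / extend 1) parameters lambda = 0.267, K = 0.041.  For
nucleotide searches lambda is solved from the scoring system itself
(ungapped, uniform base composition) and K is fixed at 0.46, the
conventional value for +1/-2 scoring; gapped nucleotide e-values are
therefore approximate, which is adequate for thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

# gapped BLOSUM62, gap open 11 / extend 1
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041

LN2 = math.log(2.0)


@dataclass(frozen=True)
class AlignmentStats:
    """Score statistics for one search (fixed scoring system and space)."""

    lam: float
    k: float
    m: int  # total database residues
    n: int  # total query residues

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / LN2

    def evalue(self, raw_score: float) -> float:
        b = self.bitscore(raw_score)
        # 2**(-b) underflows gracefully via math.exp guard
        if b > 1022:
            return 0.0
        return self.m * self.n * 2.0 ** (-b)

    def min_score_for_evalue(self, evalue_max: float) -> float:
        """Smallest raw score whose e-value is <= evalue_max (real-valued)."""
        mn = max(self.m * self.n, 1)
        b = math.log2(mn / evalue_max)
        return (b * LN2 + math.log(self.k)) / self.lam


def protein_stats(m: int, n: int) -> AlignmentStats:
    return AlignmentStats(BLOSUM62_GAPPED_LAMBDA, BLOSUM62_GAPPED_K, m, n)


def nucleotide_lambda(match: float = 1.0, mismatch: float = -2.0) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform bases."""

    def f(lam: float) -> float:
        return (4 * math.exp(lam * match) + 12 * math.exp(lam * mismatch)) / 16.0 - 1.0

    return brentq(f, 1e-6, 10.0)


def nucleotide_stats(m: int, n: int, match: float = 1.0, mismatch: float = -2.0
                     ) -> AlignmentStats:
    return AlignmentStats(nucleotide_lambda(match, mismatch), 0.46, m, n)
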