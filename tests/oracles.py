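"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain-Python dynamic
programming, direct formula evaluation, and exhaustive enumeration.
"""

from __future__ import annotations

import math

from scipy.stats import hypergeom


def sw_affine_score(query: str, subject: str, matrix, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Brute-force Smith-Waterman with affine gaps (gap of g costs open+g*ext)."""
    m, n = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (subject consumed)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + matrix[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def chisq_gof(counts) -> float:
    """One-way goodness-of-fit statistic against equal expectation."""
    total = sum(counts)
    k = len(counts)
    expected = total / k
    return sum((o - expected) ** 2 / expected for o in counts)


def chisq_independence(table) -> float:
    """Two-way independence statistic by direct O/E evaluation."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    stat = 0.0
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            e = r * c / total
            stat += (table[i][j] - e) ** 2 / e
    return stat


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums probabilities of all tables with the same margins whose probability
    does not exceed that of the observed table (within a small relative
    tolerance for float ties).
    """
    row1 = a + b
    n = a + b + c + d
    col1 = a + c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, hand-evaluated."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def karlin_altschul_evalue(score: float, m: int, n: int, lam: float, K: float) -> float:
    return K * m * n * math.exp(-lam * score)
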