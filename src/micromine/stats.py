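"""Prevalence and enrichment statistics for microcin survey count tables.

Given per-category assembly totals and microcin-positive counts (e.g. per
isolation habitat or per phylogroup): one-way goodness-of-fit and two-way
independence chi-square tests (no continuity correction), Pearson residual
matrices, log10 proportion-ratio enrichment against the global positive
rate, and pairwise two-sided Fisher's exact tests with Benjamini-Hochberg
FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "CountTable",
    "EnrichmentResult",
    "oneway_chisq",
    "twoway_chisq",
    "log_enrichment",
    "pairwise_fisher_fdr",
]


@dataclass
class CountTable:
    """Per-category assembly totals and microcin-positive counts."""

    categories: list[str]
    totals: np.ndarray
    positives: np.ndarray

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.positives = np.asarray(self.positives, dtype=np.int64)
        if len(self.categories) != len(set(self.categories)):
            raise DataError("category labels must be unique")
        if not (len(self.categories) == self.totals.size == self.positives.size):
            raise DataError("categories, totals and positives must align")
        if (self.positives < 0).any() or (self.positives > self.totals).any():
            raise DataError("need 0 <= positives <= totals per category")

    @property
    def grand_total(self) -> int:
        return int(self.totals.sum())

    @property
    def grand_positives(self) -> int:
        return int(self.positives.sum())

    @property
    def p_global(self) -> float:
        """Global proportion of microcin-positive assemblies, M/A."""
        return self.grand_positives / self.grand_total

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        """Read columns category, total_assemblies, microcin_assemblies."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"category", "total_assemblies", "microcin_assemblies"}
        if not required <= set(df.columns):
            raise DataError(f"count table needs columns {sorted(required)}")
        return cls(
            categories=df["category"].astype(str).tolist(),
            totals=df["total_assemblies"].to_numpy(),
            positives=df["microcin_assemblies"].to_numpy(),
        )


@dataclass
class EnrichmentResult:
    """A chi-square test with per-cell Pearson residuals."""

    statistic: float
    df: int
    p_value: float
    expected: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)  # (O - E) / sqrt(E)


def oneway_chisq(counts) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square against equal frequencies.

    Returns (statistic, df, p_value) with df = k - 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise DataError("one-way test needs at least 2 categories")
    if (counts < 0).any():
        raise DataError("counts must be non-negative")
    if counts.sum() <= 0:
        raise DataError("all counts are zero")
    stat, p = sps.chisquare(counts)
    return float(stat), counts.size - 1, float(p)


def twoway_chisq(table) -> EnrichmentResult:
    """Chi-square test of independence on an r x c contingency table.

    For microcin prevalence the table is 2 x k: (positives, negatives) per
    category. No continuity correction. Residuals are (O - E) / sqrt(E).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise DataError("two-way test needs an r x c table with r, c >= 2")
    if (table < 0).any():
        raise DataError("cell counts must be non-negative")
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise DataError("degenerate margins: a row or column sums to zero")
    stat, p, df, expected = sps.chi2_contingency(table, correction=False)
    residuals = (table - expected) / np.sqrt(expected)
    return EnrichmentResult(
        statistic=float(stat), df=int(df), p_value=float(p),
        expected=expected, residuals=residuals,
    )


def log_enrichment(ct: CountTable) -> pd.Series:
    """log10 of each category's positive proportion over the global one.

    0 means the category matches the global rate; categories with zero
    positives give -inf (treat as missing).
    """
    if (ct.totals == 0).any():
        raise DataError("every category needs at least one assembly")
    if ct.p_global <= 0:
        raise DataError("global positive proportion is zero")
    with np.errstate(divide="ignore"):
        values = np.log10((ct.positives / ct.totals) / ct.p_global)
    return pd.Series(values, index=ct.categories, name="log_enrichment")


def pairwise_fisher_fdr(
    ct: CountTable, method: str = "bh"
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise two-sided Fisher's exact tests with FDR correction.

    For each category pair the 2x2 table is
    ``[[m_c, a_c - m_c], [m_d, a_d - m_d]]``. Adjusted p-values
    (Benjamini-Hochberg by default) are returned as a symmetric per-pair
    matrix plus a per-category summary: each category against all others
    pooled, BH-adjusted over the k per-category tests.
    """
    k = len(ct.categories)
    if k < 2:
        raise DataError("pairwise tests need at least 2 categories")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        table = [
            [ct.positives[i], ct.totals[i] - ct.positives[i]],
            [ct.positives[j], ct.totals[j] - ct.positives[j]],
        ]
        raw[idx] = sps.fisher_exact(table, alternative="two-sided")[1]
    adjusted = sps.false_discovery_control(raw, method=method)
    matrix = pd.DataFrame(np.ones((k, k)), index=ct.categories, columns=ct.categories)
    for idx, (i, j) in enumerate(pairs):
        matrix.iat[i, j] = matrix.iat[j, i] = adjusted[idx]

    vs_rest_raw = np.empty(k)
    for i in range(k):
        rest_pos = ct.grand_positives - ct.positives[i]
        rest_neg = (ct.grand_total - ct.totals[i]) - rest_pos
        table = [
            [ct.positives[i], ct.totals[i] - ct.positives[i]],
            [rest_pos, rest_neg],
        ]
        vs_rest_raw[i] = sps.fisher_exact(table, alternative="two-sided")[1]
    per_category = pd.Series(
        sps.false_discovery_control(vs_rest_raw, method=method),
        index=ct.categories,
        name="adjusted_p_vs_rest",
    )
    return matrix, per_category
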