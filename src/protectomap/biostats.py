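"""Elementary summary statistics used across the pipeline.

These are the workhorse tests applied to demographics and regional counts:
2x2 chi-squared (with or without Yates continuity correction), two-sample t
and Cohen's d computed from printed group summaries (mean, SD, n),
Mann-Whitney U with a tie-corrected normal approximation, one-sample t, and
Benjamini-Hochberg FDR. Summary-based variants exist because published
tables report means and SDs, not raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD, and size of one group, as printed in a demographics table."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def chi2_2x2(table, continuity: bool = False) -> tuple[float, int, float]:
    """Chi-squared test of independence for a 2x2 count table.

    chi2 = N (|ad - bc| - c0)^2 / (r1 r2 c1 c2), with c0 = N/2 under the
    Yates continuity correction and 0 otherwise. Returns (chi2, df=1, p).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins) or n == 0:
        raise ValueError("2x2 table has an empty margin")
    c0 = n / 2.0 if continuity else 0.0
    num = max(abs(a * d - b * c) - c0, 0.0)
    chi2 = n * num ** 2 / np.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


def cohens_d_from_summary(g1: GroupSummary, g2: GroupSummary) -> float:
    """Cohen's d from group summaries, pooled-SD denominator."""
    sp2 = (((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2)
           / (g1.n + g2.n - 2))
    if sp2 == 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return (g1.mean - g2.mean) / np.sqrt(sp2)


def welch_or_pooled_t(g1: GroupSummary, g2: GroupSummary,
                      pooled: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries. Returns (t, df, p two-sided)."""
    diff = g1.mean - g2.mean
    if pooled:
        sp2 = (((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2)
               / (g1.n + g2.n - 2))
        if sp2 == 0:
            raise ValueError("zero pooled variance: t undefined")
        se = np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
        df = g1.n + g2.n - 2
    else:
        v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
        if v1 + v2 == 0:
            raise ValueError("zero variance: t undefined")
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    t = diff / se
    p = 2 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns (U of the first sample, Z, two-sided p). Z carries the sign of
    U - its null mean, so negative Z means the first sample ranks lower.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:  # all values tied
        return float(u1), 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2 * float(stats.norm.sf(abs(z)))
    return float(u1), float(z), min(p, 1.0)


def one_sample_t(x, popmean: float = 0.0) -> tuple[float, float]:
    """One-sample t-test against a fixed mean. Returns (t, p two-sided)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 observations")
    res = stats.ttest_1samp(x, popmean)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
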