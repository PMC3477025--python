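"""Univariate group comparisons: two-sample t-tests, a chi-square test for
the categorical allele count, per-feature summary tables, and the t-test
feature-ranking baseline.

The t-test accepts published summary statistics (n, mean, sd per group)
directly, so printed cohort tables are usable as inputs.  Default variant is
the classical pooled two-sample t; Welch is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FeatureTable

__all__ = [
    "GroupSummary",
    "two_sample_t",
    "chi_square_counts",
    "summarize_by_group",
    "rank_by_ttest",
]


@dataclass(frozen=True)
class GroupSummary:
    """One row of a baseline-characteristics table."""

    feature: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    statistic: float
    df: float
    p_value: float
    test: str = "t"
    degenerate: bool = False


def two_sample_t(n1: int, mean1: float, sd1: float,
                 n2: int, mean2: float, sd2: float,
                 variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, two-sided p).

    ``pooled`` uses the pooled-variance statistic with df = n1+n2-2; ``welch``
    uses the Welch-Satterthwaite approximation.  Degenerate input (both SDs
    zero) returns t=0, p=1 when the means agree and p=0 otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return np.inf if mean1 > mean2 else -np.inf, float(n1 + n2 - 2), 0.0
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def chi_square_counts(counts: np.ndarray) -> tuple[float, int, float, bool]:
    """Pearson chi-square on a 2 x k count table, no continuity correction.

    Returns (chi2, df, p, low_expected_flag); the flag marks any expected
    cell below 1 (the result is still returned).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero row or column")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p), bool((expected < 1).any())


def summarize_by_group(table: FeatureTable, variant: str = "pooled"
                       ) -> list[GroupSummary]:
    """One summary row per feature, comparing converters (+1) against
    non-converters (-1) on pairwise-complete data.

    Continuous features get the two-sample t-test; ``apoe``-tagged features
    are treated as categorical counts and tested with the chi-square test.
    """
    out: list[GroupSummary] = []
    y = table.labels
    for j, (name, tag) in enumerate(zip(table.feature_names, table.modality_tags)):
        col = table.X[:, j]
        ok = ~np.isnan(col)
        g1 = col[ok & (y == -1)]
        g2 = col[ok & (y == 1)]
        if tag == "apoe":
            cats = np.unique(col[ok])
            counts = np.array([[np.sum(g == c) for c in cats] for g in (g1, g2)])
            chi2, df, p, low = chi_square_counts(counts)
            out.append(GroupSummary(name, len(g1), float(g1.mean()), float(g1.std(ddof=1)),
                                    len(g2), float(g2.mean()), float(g2.std(ddof=1)),
                                    chi2, float(df), p, test="chi2", degenerate=low))
            continue
        m1, s1 = float(g1.mean()), float(g1.std(ddof=1))
        m2, s2 = float(g2.mean()), float(g2.std(ddof=1))
        # snap numerically-constant columns to exact zero spread
        scale = max(abs(m1), abs(m2), 1.0)
        s1 = 0.0 if s1 < 1e-12 * scale else s1
        s2 = 0.0 if s2 < 1e-12 * scale else s2
        degenerate = s1 == 0.0 and s2 == 0.0
        t, df, p = two_sample_t(len(g1), m1, s1, len(g2), m2, s2, variant=variant)
        out.append(GroupSummary(name, len(g1), m1, s1, len(g2), m2, s2,
                                t, df, p, degenerate=degenerate))
    return out


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Tabular form mirroring a baseline-characteristics table."""
    return pd.DataFrame([
        {
            "feature": s.feature,
            "nonconverter": f"{s.mean1:.2f} ± {s.sd1:.2f}",
            "converter": f"{s.mean2:.2f} ± {s.sd2:.2f}",
            "statistic": s.statistic,
            "p_value": s.p_value,
            "test": s.test,
        }
        for s in summaries
    ])


def rank_by_ttest(table: FeatureTable, variant: str = "pooled") -> list[str]:
    """Features ordered by |t| descending (the univariate ranking baseline).

    Constant features (no variability in either group) sort last; ties break
    by column order.  The ranking is invariant to positive rescaling of any
    feature, since t is scale-free.
    """
    summaries = summarize_by_group(table, variant=variant)
    keys = []
    for j, s in enumerate(summaries):
        if s.test == "chi2":
            # rank categorical features by the equivalent allele-count t
            t, _, _ = two_sample_t(s.n1, s.mean1, s.sd1, s.n2, s.mean2, s.sd2,
                                   variant=variant)
            mag = abs(t)
        elif s.degenerate and s.mean1 == s.mean2:
            mag = -1.0  # overall-constant features last
        else:
            mag = abs(s.statistic)
        keys.append((-mag, j))
    order = sorted(range(len(keys)), key=lambda j: keys[j])
    return [table.feature_names[j] for j in order]
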